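import pytest

from xsm.synthetic_campaign import CampaignConfig, generate_campaign


@pytest.fixture(scope="session")
def campaign():
    """A mid-sized default-parameter campaign shared across tests."""
    cfg = CampaignConfig(n_targets=60, seed=11)
    return generate_campaign(cfg)


@pytest.fixture(scope="session")
def tiny_campaign():
    """A small campaign for round-trip and CLI tests."""
    cfg = CampaignConfig(n_targets=6, seed=5)
    return generate_campaign(cfg)


@pytest.fixture()
def campaign_dir(tiny_campaign, tmp_path):
    from xsm.synthetic_campaign import write_campaign

    write_campaign(tiny_campaign, tmp_path)
    return tmp_path
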