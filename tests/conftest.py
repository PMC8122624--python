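import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fatiguemark as fm

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_session():
    """One 40-trial session with all class effects on (artifacts off)."""
    cfg = fm.GeneratorConfig(n_trials=40, seed=11, target_incorrect_fraction=0.5)
    return fm.generate_session(cfg)


@pytest.fixture(scope="session")
def small_table(small_session):
    session, events, truth = small_session
    epochs = fm.extract_epochs(session, events, "delay", 1.0)
    return fm.extract_features(epochs)


def make_toy_table(
    n_trials: int = 100,
    n_noise: int = 15,
    informative: bool = True,
    seed: int = 0,
    separation: float = 3.0,
):
    """Small synthetic feature table: optional informative column 'sig.LO'
    plus band-power-named noise columns, with a valid registry."""
    from fatiguemark.biomarkers import FeatureInfo, FeatureTable
    import pandas as pd

    rng = np.random.default_rng(seed)
    y = (np.arange(n_trials) % 2).astype(int)
    cols, reg = {}, {}
    if informative:
        cols["delta.LO"] = rng.normal(0, 1, n_trials) + separation * y
        reg["delta.LO"] = FeatureInfo("delta", ("LO",), "delta")
    chans = ["RO", "LT", "RT", "LFL", "LFM", "RFL", "RFM", "FZ", "CZ"]
    fams = ["theta", "alpha", "low_beta", "high_beta", "low_gamma"]
    i = 0
    while len(cols) < n_noise + int(informative):
        fam = fams[i % len(fams)]
        ch = chans[i % len(chans)]
        name = f"{fam}.{ch}.{i}" if f"{fam}.{ch}" in cols else f"{fam}.{ch}"
        cols[name] = rng.normal(0, 1, n_trials)
        reg[name] = FeatureInfo(fam, (ch,), fam)
        i += 1
    return FeatureTable(values=pd.DataFrame(cols), labels=y, registry=reg)
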