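import numpy as np
import pytest

from seegtag.simulate import ContactTruth, StudyConfig, simulate_study


def make_truth(seed=0, roi="STG", hemisphere="L", locked=None, hg=None, **kw):
    """Convenience ContactTruth factory for tests."""
    return ContactTruth(
        contact_id=kw.pop("contact_id", f"t{seed}"),
        subject_id="sub-01",
        roi=roi,
        hemisphere=hemisphere,
        locked_tags=locked or {},
        hg_modulated_tags=hg or {},
        seed=seed,
        **kw,
    )


@pytest.fixture(scope="session")
def tiny_study(tmp_path_factory):
    """A small on-disk synthetic study shared by I/O and CLI tests."""
    root = tmp_path_factory.mktemp("tiny_study")
    config = StudyConfig(
        n_subjects=2,
        contact_counts=(4, 3),
        hemispheres=("L", "LR"),
        sfreqs=(512.0, 512.0),
        n_trials=8,
    )
    study = simulate_study(config, master_seed=321, out_dir=root)
    return root, study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
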