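import pytest

from implantkinetics import SyntheticConfig, generate_cohort


def make_config(**overrides) -> SyntheticConfig:
    """Small-cohort config for fast tests; overrides win."""
    base = dict(n_patients=4, n_missing_ct3=0, seed=11)
    base.update(overrides)
    return SyntheticConfig(**base)


def noiseless_overrides(**extra) -> dict:
    d = dict(
        cc_slip_sd_mm=0.0,
        shift_translation_sd_mm=0.0,
        shift_rotation_sd_deg=0.0,
        recon_noise_sd_mm=0.0,
        marker_noise_sd_mm=0.0,
    )
    d.update(extra)
    return d


@pytest.fixture(scope="session")
def small_cohort():
    """Four noisy patients with default deformation parameters."""
    cohort, truths = generate_cohort(make_config())
    return cohort, truths


@pytest.fixture(scope="session")
def null_cohort():
    """Zero expansion, zero noise, zero shift: all scans coincide."""
    cfg = make_config(
        true_dv_percent_ct2=0.0, true_dv_percent_ct3=0.0, **noiseless_overrides()
    )
    cohort, truths = generate_cohort(cfg)
    return cohort, truths
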