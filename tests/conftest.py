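"""Shared fixtures: small seeded cohorts and window sets, built once."""

import numpy as np
import pytest

from dualgait.preprocessing import windows_from_cohort
from dualgait.synthetic import (
    CohortSpec,
    archetype,
    cohort_manifest,
    make_cohort,
    simulate_recording,
)


@pytest.fixture(scope="session")
def default_cohort():
    """A 60-subject cohort at the default class composition (120 s each)."""
    return make_cohort(CohortSpec(master_seed=7))


@pytest.fixture(scope="session")
def default_manifest(default_cohort):
    return cohort_manifest(default_cohort)


@pytest.fixture(scope="session")
def clean_recording():
    """One noiseless, drift-free healthy recording (60 s)."""
    arch = archetype("healthy", noise_sigma=0.0, drift_sigma=0.0)
    return simulate_recording(arch, 60.0, "S000", seed=11)


@pytest.fixture(scope="session")
def small_separable_windows():
    """Preprocessed windows from a small, strongly separable 2-class cohort."""
    spec = CohortSpec(
        class_counts={"healthy": 6, "pd_ar": 6},
        duration_s=60.0,
        master_seed=3,
        overrides={
            "healthy": {"noise_sigma": 0.02, "drift_sigma": 0.005},
            "pd_ar": {"noise_sigma": 0.02, "drift_sigma": 0.005},
        },
    )
    cohort = make_cohort(spec)
    return windows_from_cohort(cohort), cohort_manifest(cohort)


def factor_cohort(n_per=6, duration=60.0, master_seed=0, degenerate=False):
    """Cohort whose classes are a 2x2 design of modality-specific cues.

    Factor P lives only in the plantar channel (polarity flip of the
    triboelectric pulse train); factor S lives only in the strain channels
    (tremor overlay).  Each single modality can resolve its own factor only,
    while the fused input separates all classes.  With ``degenerate=True``
    the plantar factor is dropped, leaving all class signal in the strain
    channels.
    """
    recs = []
    idx = 0
    for p_flip in (False, True):
        if degenerate and p_flip:
            continue
        for tremor in (False, True):
            label = f"c{int(p_flip)}{int(tremor)}"
            for _ in range(n_per):
                arch = archetype(
                    "healthy",
                    noise_sigma=0.02,
                    drift_sigma=0.005,
                    tremor_hz=3.5 if tremor else 0.0,
                    tremor_amp=0.5 if tremor else 0.0,
                )
                seed = np.random.SeedSequence([master_seed, idx])
                rec = simulate_recording(arch, duration, f"S{idx:03d}", seed)
                if p_flip:
                    rec.channels[0] = -rec.channels[0]
                rec.class_label = label
                recs.append(rec)
                idx += 1
    return recs
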