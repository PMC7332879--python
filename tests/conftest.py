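"""Shared fixtures: hand-built runs with planted Gaussian peaks, and a
small ground-truthed synthetic study."""

from __future__ import annotations

import numpy as np
import pytest

from residomics.io import CentroidRun, CentroidScan, RunMetadata
from residomics.simulate import SimConfig, make_study


def make_peak_run(
    peaks,
    run_id: str = "test_run",
    rt_start: float = 0.01,
    rt_end: float = 12.5,
    scan_interval: float = 0.011,
    peak_width: float = 0.05,
    floor: float = 1.0,
    metadata: RunMetadata | None = None,
) -> CentroidRun:
    """Build a run with exact Gaussian peaks at (mz, rt, apex_height).

    Scan times are placed so that one scan falls exactly on each peak's
    apex RT is NOT guaranteed; callers needing an exact apex sample should
    choose rt on the scan grid (rt_start + k * scan_interval).
    """
    rts = np.arange(rt_start, rt_end + scan_interval / 2, scan_interval)
    scans = []
    for i, rt in enumerate(rts):
        mzs, ints = [], []
        for mz, apex_rt, height in peaks:
            inten = height * np.exp(-0.5 * ((rt - apex_rt) / peak_width) ** 2)
            if inten >= floor:
                mzs.append(mz)
                ints.append(inten)
        order = np.argsort(mzs)
        scans.append(CentroidScan(
            index=i + 1, rt=float(rt),
            mz=np.asarray(mzs)[order] if mzs else np.empty(0),
            intensity=np.asarray(ints)[order] if mzs else np.empty(0),
        ))
    meta = metadata or RunMetadata(run_id=run_id)
    return CentroidRun(metadata=meta, scans=scans)


SMALL_CONFIG = SimConfig(
    species=("NQU", "RGL", "TBR"),
    compounds_per_species=20,
    replicates=2,
    blank_compounds=10,
    contaminant_compounds=5,
    mixtures={"ANC": {"NQU": 0.6, "RGL": 0.4}},
    dropout=0.2,
    seed=11,
)


@pytest.fixture(scope="session")
def small_study():
    """A small full-design study (3 species x 3 solvents x 2 replicates,
    blanks, QC pools, one ancient mixture) with ground truth."""
    return make_study(SMALL_CONFIG)
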