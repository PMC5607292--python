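"""Shared fixtures: toy amplicons, small simulated cohorts, oracle helpers."""

from __future__ import annotations

import functools

import numpy as np
import pytest

from cryptdrift.amplicon import AmpliconSpec, convert_reference, default_amplicon_spec
from cryptdrift.simulate import AssayParams, CohortDesign, simulate_cohort


@pytest.fixture(scope="session")
def toy_spec() -> AmpliconSpec:
    """20-bp amplicon with 2 CpG sites and 2 control cytosines."""
    #              C at 1 (CpG), 5 (control), 9 (CpG), 14 (control)
    return AmpliconSpec(
        name="toy",
        reference_seq="ACGTACATTCGATGCATGAT",
        cpg_positions=(1, 9),
        control_positions=(5, 14),
    )


@pytest.fixture(scope="session")
def default_spec() -> AmpliconSpec:
    return default_amplicon_spec()


@pytest.fixture(scope="session")
def quick_cohort():
    """Small noiseless cohort reused across tests (2x2 patients, 2 crypts,
    shallow depth, zero assay error)."""
    design = CohortDesign(
        n_patients_per_group=2, n_crypts_per_patient=2,
        assay=AssayParams(depth_meanlog=np.log(200.0), depth_sdlog=0.3,
                          depth_min=50, depth_max=1000,
                          p_conversion_failure=0.0,
                          p_inappropriate_conversion=0.0, p_seq_error=0.0),
    )
    return simulate_cohort(design, seed=11)


def oracle_align_score(read: str, refseq: str, cpg: frozenset,
                       match=1.0, mismatch=-1.0, gap=-2.0) -> float:
    """Independent exhaustive-DP global alignment score (recursive with
    memoisation) for validating the production aligner."""

    @functools.lru_cache(maxsize=None)
    def f(i: int, j: int) -> float:
        if i == 0:
            return gap * j
        if j == 0:
            return gap * i
        rb, qb = refseq[i - 1], read[j - 1]
        ok = qb == rb or (rb == "C" and (i - 1) in cpg and qb == "T")
        return max(
            f(i - 1, j - 1) + (match if ok else mismatch),
            f(i - 1, j) + gap,
            f(i, j - 1) + gap,
        )

    return f(len(refseq), len(read))


@pytest.fixture(scope="session")
def oracle_aligner():
    return oracle_align_score
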