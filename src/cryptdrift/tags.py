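"""Per-crypt methylation-tag analysis.

A crypt's passed reads are tabulated into a pattern frequency table
(pattern = the ordered M/U states of the CpG sites in one read, an
epiallele).  Patterns below an error-frequency cutoff (default 1% of the
crypt's passed reads) are treated as PCR/sequencing artefacts and removed.
Two summary statistics follow:

* **diversity** — the number of distinct retained patterns; a proxy for
  time since the crypt's stem cells last shared a common ancestor (niche
  succession).
* **percent methylation** — methylated CpG site-calls over total CpG
  site-calls; a proxy for mitotic age.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CRYPT_TABLE_COLUMNS = [
    "crypt_id", "patient_id", "group", "timepoint_label", "timepoint_years",
    "depth", "diversity", "percent_methylation_readweighted",
    "percent_methylation_patternweighted", "passed_depth_filter",
]


@dataclass
class CryptProfile:
    """Pattern frequency table and derived statistics for one crypt."""

    crypt_id: str
    patient_id: str = ""
    group: str = ""
    timepoint_label: str = ""
    timepoint_years: float = float("nan")
    pattern_table: dict[str, int] = field(default_factory=dict)
    retained_patterns: dict[str, int] = field(default_factory=dict)
    diversity: int = 0
    percent_methylation: float = float("nan")
    percent_methylation_patternweighted: float = float("nan")
    passed_depth_filter: bool = True

    @property
    def depth(self) -> int:
        return sum(self.pattern_table.values())


def tabulate_patterns(patterns: Iterable[str]) -> dict[str, int]:
    """Exact multiset count of distinct patterns for one crypt.

    An empty input yields an empty table; callers flag such crypts and
    exclude them downstream.
    """
    table = dict(Counter(patterns))
    if not table:
        logger.warning("crypt with zero passed reads: empty pattern table")
    if any(not p for p in table):
        raise ValueError("empty pattern string in input")
    return table


def apply_frequency_cutoff(pattern_table: Mapping[str, int],
                           cutoff_fraction: float = 0.01) -> dict[str, int]:
    """Retain patterns whose frequency is >= ``cutoff_fraction`` of the
    crypt's total passed reads (boundary inclusive; a pattern at exactly
    the cutoff is kept).  The denominator is the total pre-cutoff depth.
    """
    if cutoff_fraction < 0:
        raise ValueError("cutoff_fraction must be >= 0")
    depth = sum(pattern_table.values())
    if depth == 0:
        return {}
    return {p: c for p, c in pattern_table.items() if c / depth >= cutoff_fraction}


def compute_diversity(retained_patterns: Mapping[str, int]) -> int:
    """Number of distinct retained methylation patterns in the crypt."""
    d = len(retained_patterns)
    if d == 0:
        logger.warning("degenerate crypt: zero retained patterns")
    return d


def compute_percent_methylation(patterns: Mapping[str, int],
                                weighting: str = "reads") -> float:
    """Percent of methylated CpG site-calls, 0..100.

    ``weighting="reads"`` counts each read's sites (the natural analogue of
    clone-based scoring); ``"patterns"`` counts each distinct pattern once.
    Pass the pre- or post-cutoff table to control the scope.
    """
    if not patterns:
        raise ValueError("empty pattern table")
    lengths = {len(p) for p in patterns}
    if len(lengths) != 1:
        raise ValueError("patterns of unequal length")
    if weighting == "reads":
        meth = sum(p.count("M") * c for p, c in patterns.items())
        total = sum(len(p) * c for p, c in patterns.items())
    elif weighting == "patterns":
        meth = sum(p.count("M") for p in patterns)
        total = sum(len(p) for p in patterns)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return 100.0 * meth / total


def profile_crypt(
    crypt_id: str,
    patterns: Iterable[str],
    cutoff_fraction: float = 0.01,
    meta: Mapping[str, object] | None = None,
) -> CryptProfile:
    """Tabulate, cut off, and summarize one crypt's passed read patterns."""
    table = tabulate_patterns(patterns)
    retained = apply_frequency_cutoff(table, cutoff_fraction)
    meta = dict(meta or {})
    prof = CryptProfile(
        crypt_id=crypt_id,
        patient_id=str(meta.get("patient_id", "")),
        group=str(meta.get("group", "")),
        timepoint_label=str(meta.get("timepoint_label", "")),
        timepoint_years=float(meta.get("timepoint_years", float("nan"))),
        pattern_table=table,
        retained_patterns=retained,
        diversity=compute_diversity(retained),
    )
    if retained:
        prof.percent_methylation = compute_percent_methylation(retained, "reads")
        prof.percent_methylation_patternweighted = compute_percent_methylation(
            retained, "patterns")
    return prof


def crypt_table(
    calls: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    cutoff_fraction: float = 0.01,
    min_depth: float = 0,
) -> pd.DataFrame:
    """Aggregate a passed-read call table into the crypt-level table.

    ``calls`` needs columns sample_id + pattern; ``sample_sheet`` maps
    sample_id -> patient_id, group, timepoint_label, timepoint_years.
    Crypts with zero retained patterns are excluded with a logged reason
    (a sampled crypt always carries at least one true lineage; zero marks
    assay failure, not biology).
    """
    required = {"sample_id", "patient_id", "group", "timepoint_label", "timepoint_years"}
    missing = required - set(sample_sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    rows = []
    grouped = dict(list(calls.groupby("sample_id")["pattern"]))
    for _, srow in sample_sheet.iterrows():
        cid = srow["sample_id"]
        pats = list(grouped.get(cid, []))
        if not pats:
            logger.warning("crypt %s: zero passed reads; excluded", cid)
            continue
        prof = profile_crypt(cid, pats, cutoff_fraction, meta=srow.to_dict())
        if prof.diversity == 0:
            logger.warning("crypt %s: zero retained patterns; excluded", cid)
            continue
        rows.append({
            "crypt_id": cid,
            "patient_id": srow["patient_id"],
            "group": srow["group"],
            "timepoint_label": srow["timepoint_label"],
            "timepoint_years": float(srow["timepoint_years"]),
            "depth": prof.depth,
            "diversity": prof.diversity,
            "percent_methylation_readweighted": prof.percent_methylation,
            "percent_methylation_patternweighted": prof.percent_methylation_patternweighted,
            "passed_depth_filter": prof.depth >= min_depth,
        })
    return pd.DataFrame(rows, columns=CRYPT_TABLE_COLUMNS)


def depth_sensitivity_filter(crypts: pd.DataFrame,
                             min_depth: int = 1000) -> pd.DataFrame:
    """Retain crypts with sequencing depth >= ``min_depth`` (sensitivity
    re-analysis); logs retained/total counts."""
    kept = crypts[crypts["depth"] >= min_depth].copy()
    logger.info("depth filter >=%dx: retained %d of %d crypts",
                min_depth, len(kept), len(crypts))
    return kept


def clone_subsample(
    patterns: Sequence[str],
    n_clones: int = 10,
    seed: int | np.random.Generator = 0,
    crypt_id: str = "",
    meta: Mapping[str, object] | None = None,
) -> CryptProfile:
    """Sanger-style clone mode: sample ``n_clones`` reads uniformly without
    replacement and summarize them with no frequency cutoff (each cloned
    molecule counts, mirroring a 10-clone sequencing workflow).  Fewer
    passed reads than ``n_clones`` takes all, with a warning."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    patterns = list(patterns)
    if len(patterns) < n_clones:
        logger.warning("crypt %s: only %d reads for %d-clone subsample",
                       crypt_id, len(patterns), n_clones)
        chosen = patterns
    else:
        idx = rng.choice(len(patterns), size=n_clones, replace=False)
        chosen = [patterns[i] for i in sorted(idx)]
    return profile_crypt(crypt_id, chosen, cutoff_fraction=0.0, meta=meta)
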