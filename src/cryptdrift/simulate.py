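"""Synthetic cohort generator: crypt stem-cell niches under neutral drift,
with a bisulfite-amplicon sequencing assay overlaid.

The niche model is a discrete-event Moran process: a crypt is maintained by
``n_stem`` equipotent stem cells; at each replacement event a random cell
dies and is replaced by the daughter of a random surviving cell.  Daughters
inherit the parent's CpG methylation pattern with independent per-site
gain/loss errors, so patterns diverge with time and re-homogenize when one
lineage sweeps the niche (niche succession).  The event count over a
duration is Poisson(replacement_rate x n_stem x duration).

The assay layer draws a lognormal read depth per crypt, samples cells
uniformly per read, renders each cell's epigenotype onto the converted
reference (M -> C, U -> T at CpG sites), and overlays the artefact sources
that the 1% frequency cutoff is meant to remove: incomplete bisulfite
conversion (modelled per molecule — an under-converted read retains C at a
random subset of its unmethylated cytosines, which is why control-site
filtering catches most of them), inappropriate conversion of methylated
cytosines, and uniform per-base sequencing error.

Every emitted read's source cell is recorded, so ground truth is exact.
Reproducibility: one global seed expands to per-crypt substreams via
``np.random.SeedSequence(seed, spawn_key=(crypt_index,))`` (crypts are
enumerated group -> patient -> timepoint -> crypt); any crypt can be
regenerated in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .amplicon import AmpliconSpec, ConvertedReference, convert_reference, default_amplicon_spec
from . import tags
from .readproc import write_fastq

logger = logging.getLogger(__name__)

GROUPS = ("placebo", "sulindac")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class NicheParams:
    """Stem-cell niche drift parameters.

    replacement_rate is per stem cell per year (events per niche-year =
    replacement_rate x n_stem).  mu_gain / mu_loss are per-site methylation
    gain/loss rates per year of lineage time: crypt cells divide
    continuously whatever the stem-replacement rate, so error accrual is
    clocked by calendar time, while replacement events copy patterns and
    only homogenize the niche.  (Tying errors to replacement events instead
    makes diversity *increase* with the replacement rate — the mutation
    injection outpaces homogenization — inverting the niche-succession
    logic the assay rests on.)  t_burnin years of pre-study drift stand in
    for the crypt's age; ancestor_methylation sets the founder lineage's
    per-site methylation probability (mitotic age accumulated before the
    niche was founded).
    """

    n_stem: int = 8
    replacement_rate: float = 0.35
    mu_gain: float = 0.02
    mu_loss: float = 0.005
    n_cpg: int = 8
    t_burnin: float = 3.0
    ancestor_methylation: float = 0.15

    def __post_init__(self):
        if self.n_stem < 1:
            raise ValueError("n_stem must be >= 1")
        for name in ("mu_gain", "mu_loss", "ancestor_methylation"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.replacement_rate < 0 or self.t_burnin < 0:
            raise ValueError("rates and durations must be >= 0")


@dataclass
class AssayParams:
    """Sequencing-assay noise model.

    Depth is lognormal(meanlog, sdlog) clipped to [depth_min, depth_max],
    emulating the wide per-crypt coverage spread of amplicon runs (defaults
    span roughly 4 to 50,000 reads).  p_conversion_failure is the
    per-molecule probability that bisulfite conversion was incomplete; in
    such a molecule each unmethylated C independently survives as C with
    probability within_read_conversion_failure.  p_inappropriate_conversion
    converts a methylated C to T per site; p_seq_error is the per-base
    substitution rate.
    """

    depth_meanlog: float = 8.2
    depth_sdlog: float = 1.6
    depth_min: int = 1
    depth_max: int = 50000
    p_conversion_failure: float = 0.01
    within_read_conversion_failure: float = 0.5
    p_inappropriate_conversion: float = 0.005
    p_seq_error: float = 0.001

    def __post_init__(self):
        for name in ("p_conversion_failure", "within_read_conversion_failure",
                     "p_inappropriate_conversion", "p_seq_error"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class CohortDesign:
    """Two-arm longitudinal design: placebo vs sulindac, cross-sectional
    crypts per patient per timepoint.  Sulindac is modelled as accelerated
    stem-cell replacement (earlier niche succession), which flattens the
    diversity trend relative to placebo."""

    n_patients_per_group: int = 4
    n_crypts_per_patient: int = 10
    timepoints_years: tuple[float, ...] = (0.0, 1.0 / 3.0, 2.0)
    timepoint_labels: tuple[str, ...] = ("t0", "t4m", "t2y")
    sulindac_rate_multiplier: float = 4.0
    polyp_slope_per_year: dict = field(
        default_factory=lambda: {"placebo": 6.0, "sulindac": 0.3})
    polyp_slope_sdlog: float = 0.5
    niche: NicheParams = field(default_factory=NicheParams)
    assay: AssayParams = field(default_factory=AssayParams)

    @property
    def n_crypts_total(self) -> int:
        return (2 * self.n_patients_per_group * len(self.timepoints_years)
                * self.n_crypts_per_patient)


@dataclass
class CohortData:
    """In-memory synthetic dataset (also writable to a run directory)."""

    reads: list  # (read_id, seq, qual)
    spec: AmpliconSpec
    sample_sheet: pd.DataFrame
    polyps: pd.DataFrame
    truth_crypts: pd.DataFrame
    truth_patterns: pd.DataFrame
    design: CohortDesign
    seed: int


def simulate_niche(
    params: NicheParams,
    duration_years: float,
    rng: np.random.Generator,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Evolve one niche for ``duration_years``; returns the (n_stem, n_cpg)
    boolean methylation state (True = methylated).

    With ``init=None`` the niche starts clonal: every cell carries the
    founder pattern drawn site-wise at ``ancestor_methylation``.
    """
    n, s = params.n_stem, params.n_cpg
    if init is None:
        ancestor = rng.random(s) < params.ancestor_methylation
        niche = np.tile(ancestor, (n, 1))
    else:
        niche = np.array(init, dtype=bool, copy=True)
        if niche.shape != (n, s):
            raise ValueError("init shape does not match params")

    def drift(dt: float) -> None:
        if dt <= 0 or (params.mu_gain == 0 and params.mu_loss == 0):
            return
        pg = -np.expm1(-params.mu_gain * dt)
        pl = -np.expm1(-params.mu_loss * dt)
        u = rng.random((n, s))
        gain = ~niche & (u < pg)
        loss = niche & (u < pl)
        niche[gain] = True
        niche[loss] = False

    n_events = rng.poisson(params.replacement_rate * n * duration_years)
    times = np.sort(rng.uniform(0.0, duration_years, size=n_events))
    prev = 0.0
    for t_ev in times:
        drift(t_ev - prev)
        prev = t_ev
        die = int(rng.integers(n))
        if n == 1:
            parent = 0
        else:
            parent = int(rng.integers(n - 1))
            if parent >= die:
                parent += 1
        niche[die] = niche[parent]
    drift(duration_years - prev)
    return niche


def niche_diversity(niche: np.ndarray) -> int:
    """Number of distinct epigenotypes among the niche's stem cells."""
    return len(np.unique(niche, axis=0))


def _patterns_of(cells: np.ndarray) -> list[str]:
    return ["".join("M" if m else "U" for m in row) for row in cells]


def sequence_crypt(
    niche: np.ndarray,
    assay: AssayParams,
    spec: AmpliconSpec,
    rng: np.random.Generator,
    barcode: str = "",
    crypt_id: str = "crypt",
) -> tuple[list[tuple[str, str, str]], dict]:
    """Render one crypt's niche into barcoded FASTQ records plus an exact
    truth record (per-read source patterns and niche state)."""
    ref: ConvertedReference = convert_reference(spec)
    conv = np.frombuffer(ref.converted_seq.encode(), dtype=np.uint8)
    m = conv.size
    cpg = np.asarray(spec.cpg_positions, dtype=int)
    controls = np.asarray(spec.control_positions, dtype=int)
    n_cells, n_cpg = niche.shape
    if n_cpg != len(cpg):
        raise ValueError("niche pattern width does not match assay CpG count")

    depth = int(np.clip(round(rng.lognormal(assay.depth_meanlog, assay.depth_sdlog)),
                        assay.depth_min, assay.depth_max))
    cells = rng.integers(0, n_cells, size=depth)
    pat = niche[cells]  # (depth, n_cpg) True = methylated

    reads = np.tile(conv, (depth, 1))
    C, T = ord("C"), ord("T")
    reads[:, cpg] = np.where(pat, C, T)

    # per-molecule incomplete conversion: unconverted C at a random subset
    # of the molecule's unmethylated cytosines (controls + U CpG sites)
    bad = rng.random(depth) < assay.p_conversion_failure
    if bad.any():
        w = assay.within_read_conversion_failure
        if controls.size:
            keep = bad[:, None] & (rng.random((depth, controls.size)) < w)
            block = reads[:, controls]
            block[keep] = C
            reads[:, controls] = block
        keep = bad[:, None] & ~pat & (rng.random((depth, n_cpg)) < w)
        block = reads[:, cpg]
        block[keep] = C
        reads[:, cpg] = block

    # inappropriate conversion of methylated C (reads as T)
    if assay.p_inappropriate_conversion > 0:
        flip = pat & (rng.random((depth, n_cpg)) < assay.p_inappropriate_conversion)
        block = reads[:, cpg]
        block[flip] = T
        reads[:, cpg] = block

    # uniform per-base sequencing substitution error
    if assay.p_seq_error > 0:
        err = rng.random((depth, m)) < assay.p_seq_error
        n_err = int(err.sum())
        if n_err:
            base_index = np.zeros(256, dtype=np.uint8)
            for k, b in enumerate(_BASES):
                base_index[b] = k
            cur = base_index[reads[err]]
            new = (cur + rng.integers(1, 4, size=n_err)) % 4
            reads[err] = _BASES[new]

    qual = "I" * (m + len(barcode))
    bc = barcode
    records = []
    seqs = reads.tobytes().decode()
    for k in range(depth):
        records.append((f"{crypt_id}:{k}", bc + seqs[k * m:(k + 1) * m], qual))

    true_patterns = _patterns_of(pat)
    truth = {
        "crypt_id": crypt_id,
        "depth": depth,
        "niche_diversity": niche_diversity(niche),
        "cell_mixture": dict(pd.Series(_patterns_of(niche)).value_counts()),
        "read_pattern_counts": dict(pd.Series(true_patterns).value_counts()),
    }
    return records, truth


def crypt_barcode(index: int, length: int = 8) -> str:
    """Deterministic unique equal-length barcode for crypt ``index``."""
    if index >= 4 ** length:
        raise ValueError("barcode space exhausted")
    return "".join("ACGT"[(index >> (2 * k)) & 3] for k in reversed(range(length)))


def simulate_cohort(
    design: CohortDesign | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
    cutoff_fraction: float = 0.01,
) -> CohortData:
    """Simulate the full two-arm longitudinal cohort.

    Crypts at different timepoints are distinct physical crypts (the assay
    is destructive): each is burned in for ``t_burnin`` years at the
    baseline replacement rate and then evolved for the elapsed study time
    at its group's treatment rate.  ``cutoff_fraction`` is only used to
    annotate the truth table with post-cutoff read-truth summaries.
    """
    design = design or CohortDesign()
    npg = design.n_patients_per_group

    crypt_index = 0
    reads_all: list[tuple[str, str, str]] = []
    sheet_rows, truth_rows, pattern_rows = [], [], []
    barcode_map: dict[str, str] = {}

    for group in GROUPS:
        mult = design.sulindac_rate_multiplier if group == "sulindac" else 1.0
        for p in range(npg):
            patient_id = f"{group[:2].upper()}{p + 1}"
            for t_years, t_label in zip(design.timepoints_years, design.timepoint_labels):
                for c in range(design.n_crypts_per_patient):
                    rng = np.random.default_rng(
                        np.random.SeedSequence(seed, spawn_key=(crypt_index,)))
                    crypt_id = f"{patient_id}_{t_label}_c{c + 1:02d}"
                    barcode = crypt_barcode(crypt_index)
                    barcode_map[barcode] = crypt_id

                    base = design.niche
                    niche = simulate_niche(base, base.t_burnin, rng)
                    if t_years > 0:
                        treated = NicheParams(**{**asdict(base),
                                                 "replacement_rate": base.replacement_rate * mult})
                        niche = simulate_niche(treated, t_years, rng, init=niche)

                    spec_nobc = default_amplicon_spec()
                    recs, truth = sequence_crypt(
                        niche, design.assay, spec_nobc, rng, barcode, crypt_id)
                    reads_all.extend(recs)

                    counts = truth["read_pattern_counts"]
                    retained = tags.apply_frequency_cutoff(counts, cutoff_fraction)
                    truth_rows.append({
                        "crypt_id": crypt_id,
                        "patient_id": patient_id,
                        "group": group,
                        "timepoint_label": t_label,
                        "timepoint_years": t_years,
                        "depth": truth["depth"],
                        "niche_diversity": truth["niche_diversity"],
                        "true_diversity": tags.compute_diversity(retained),
                        "true_percent_methylation":
                            tags.compute_percent_methylation(retained, "reads")
                            if retained else float("nan"),
                    })
                    for pat_s, n in sorted(counts.items()):
                        pattern_rows.append({"crypt_id": crypt_id, "pattern": pat_s,
                                             "n_reads": int(n)})
                    sheet_rows.append({
                        "sample_id": crypt_id, "patient_id": patient_id,
                        "group": group, "timepoint_label": t_label,
                        "timepoint_years": t_years, "barcode": barcode,
                    })
                    crypt_index += 1

    # per-patient polyp trajectories: linear trend with patient-level slope
    # heterogeneity, Poisson count noise, zero at baseline
    prng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2 ** 20,)))
    polyp_rows = []
    for group in GROUPS:
        for p in range(npg):
            patient_id = f"{group[:2].upper()}{p + 1}"
            slope = (design.polyp_slope_per_year[group]
                     * prng.lognormal(0.0, design.polyp_slope_sdlog))
            for t_years, t_label in zip(design.timepoints_years, design.timepoint_labels):
                count = 0 if t_years == 0 else int(prng.poisson(slope * t_years))
                polyp_rows.append({"patient_id": patient_id, "group": group,
                                   "timepoint_label": t_label,
                                   "timepoint_years": t_years, "polyps": count})

    spec = default_amplicon_spec(barcode_map)
    data = CohortData(
        reads=reads_all,
        spec=spec,
        sample_sheet=pd.DataFrame(sheet_rows),
        polyps=pd.DataFrame(polyp_rows),
        truth_crypts=pd.DataFrame(truth_rows),
        truth_patterns=pd.DataFrame(pattern_rows),
        design=design,
        seed=seed,
    )
    if outdir is not None:
        write_cohort(data, outdir)
    return data


def write_cohort(data: CohortData, outdir: str | Path) -> Path:
    """Write a simulated cohort to a run directory (FASTQ, sample sheet,
    polyp table, truth tables, reference FASTA, assay config, params)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fastq(outdir / "reads.fastq.gz", data.reads)
    data.sample_sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
    data.polyps.to_csv(outdir / "polyps.tsv", sep="\t", index=False)
    data.truth_crypts.to_csv(outdir / "truth_crypts.tsv", sep="\t", index=False)
    data.truth_patterns.to_csv(outdir / "truth_patterns.tsv", sep="\t", index=False)
    with open(outdir / "reference.fasta", "w") as fh:
        fh.write(f">{data.spec.name}\n{data.spec.reference_seq}\n")
    assay_cfg = {
        "name": data.spec.name,
        "coordinate_base": 0,
        "cpg_positions": list(data.spec.cpg_positions),
        "control_positions": list(data.spec.control_positions),
        "primer_fwd": data.spec.primer_fwd,
        "primer_rev": data.spec.primer_rev,
        "barcodes": dict(data.spec.barcode_map),
    }
    with open(outdir / "assay.yaml", "w") as fh:
        yaml.safe_dump(assay_cfg, fh, sort_keys=False)
    params = json.loads(json.dumps(
        {"seed": data.seed, "design": asdict(data.design)}))
    with open(outdir / "params.yaml", "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=False)
    return outdir


# ---------------------------------------------------------------------------
# Observed clinical-trial inputs (polyp counts and baseline ages of the
# eight pediatric FAP patients in the sulindac chemoprevention trial).
# Ages reconstructed to satisfy the published group means (9.75 / 11.5 y)
# and range (7-15 y).
# ---------------------------------------------------------------------------

_TRIAL_ROWS = [
    # patient_id, group, age, polyps at 0 / 4 months / 2 years
    ("SU1", "sulindac", 7, 0, 0, 0),
    ("SU2", "sulindac", 9, 0, 0, 0),
    ("SU3", "sulindac", 9, 0, 1, 0),
    ("SU4", "sulindac", 14, 0, 0, 5),
    ("PL1", "placebo", 8, 0, 1, 3),
    ("PL2", "placebo", 9, 0, 1, 10),
    ("PL3", "placebo", 14, 0, 15, 40),
    ("PL4", "placebo", 15, 0, 4, 7),
]


def trial_polyp_table() -> pd.DataFrame:
    """Observed per-patient polyp counts (long format) from the sulindac
    chemoprevention trial cohort, with baseline ages."""
    rows = []
    for pid, group, age, p0, p4m, p2y in _TRIAL_ROWS:
        for t_label, t_years, n in (("t0", 0.0, p0), ("t4m", 1 / 3, p4m), ("t2y", 2.0, p2y)):
            rows.append({"patient_id": pid, "group": group, "age": age,
                         "timepoint_label": t_label, "timepoint_years": t_years,
                         "polyps": n})
    return pd.DataFrame(rows)
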