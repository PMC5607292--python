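"""Amplicon assay definition and in-silico bisulfite conversion.

The assay targets a single nested-PCR amplicon containing a CpG island in a
transcriptionally silent gene.  Methylation state is read out per CpG site
from bisulfite-converted reads; non-CpG cytosines serve as conversion
controls (they must read as T in a fully converted molecule).  All internal
coordinates are 0-based offsets into the amplicon between (and excluding)
the inner PCR primers; assay configs may supply positions in 0- or 1-based
convention via ``coordinate_base``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml
from Bio import SeqIO

logger = logging.getLogger(__name__)

_DNA = set("ACGT")


@dataclass(frozen=True)
class AmpliconSpec:
    """Definition of one bisulfite amplicon assay.

    Parameters
    ----------
    name : str
        Assay name.
    reference_seq : str
        Unconverted genomic sequence of the amplicon (A/C/G/T, uppercase).
    cpg_positions : tuple of int
        0-based offsets of CpG cytosines (each C must be followed by G).
    control_positions : tuple of int
        0-based offsets of non-CpG cytosines used as bisulfite conversion
        controls (each C must NOT be followed by G).
    barcode_map : mapping
        barcode sequence -> sample identifier; barcodes must be unique and
        of equal length.
    primer_fwd, primer_rev : str
        Inner PCR primer sequences (informational; reads are expected to
        contain only barcode + amplicon).
    """

    name: str
    reference_seq: str
    cpg_positions: tuple[int, ...]
    control_positions: tuple[int, ...]
    barcode_map: Mapping[str, str] = field(default_factory=dict)
    primer_fwd: str = ""
    primer_rev: str = ""

    def __post_init__(self):
        seq = self.reference_seq.upper()
        object.__setattr__(self, "reference_seq", seq)
        if not seq or set(seq) - _DNA:
            raise ValueError("reference_seq must be a non-empty A/C/G/T string")
        object.__setattr__(self, "cpg_positions", tuple(self.cpg_positions))
        object.__setattr__(self, "control_positions", tuple(self.control_positions))
        n = len(seq)
        for p in self.cpg_positions:
            if not (0 <= p < n):
                raise ValueError(f"CpG position {p} outside [0, {n})")
            if seq[p] != "C":
                raise ValueError(f"position {p} is not a C")
            if p + 1 >= n or seq[p + 1] != "G":
                raise ValueError(f"position {p} not followed by G")
        for p in self.control_positions:
            if not (0 <= p < n):
                raise ValueError(f"control position {p} outside [0, {n})")
            if seq[p] != "C":
                raise ValueError(f"control position {p} is not a C")
            if p + 1 < n and seq[p + 1] == "G":
                raise ValueError(f"control position {p} is followed by G (CpG context)")
        if len(set(self.cpg_positions)) != len(self.cpg_positions):
            raise ValueError("duplicate CpG positions")
        if len(set(self.control_positions)) != len(self.control_positions):
            raise ValueError("duplicate control positions (deduplicate upstream)")
        if set(self.cpg_positions) & set(self.control_positions):
            raise ValueError("CpG and control positions overlap")
        if list(self.cpg_positions) != sorted(self.cpg_positions):
            raise ValueError("CpG positions must be strictly increasing")
        if list(self.control_positions) != sorted(self.control_positions):
            raise ValueError("control positions must be strictly increasing")
        bcs = list(self.barcode_map)
        if bcs:
            if len(set(bcs)) != len(bcs):
                raise ValueError("barcodes not unique")
            if len({len(b) for b in bcs}) != 1:
                raise ValueError("barcodes must have equal length")

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_positions)

    @property
    def barcode_length(self) -> int:
        if not self.barcode_map:
            raise ValueError("no barcodes configured")
        return len(next(iter(self.barcode_map)))


@dataclass(frozen=True)
class ConvertedReference:
    """Fully-methylated in-silico bisulfite conversion of an amplicon.

    Every non-CpG C of the reference is replaced by T; CpG cytosines are
    retained as C (fully methylated assumption), so converted reads align
    against it with a C/T ambiguity only at CpG sites.
    """

    converted_seq: str
    source: AmpliconSpec

    def __post_init__(self):
        if len(self.converted_seq) != len(self.source.reference_seq):
            raise ValueError("converted sequence length mismatch")
        cpg = set(self.source.cpg_positions)
        for i, b in enumerate(self.converted_seq):
            if b == "C" and i not in cpg:
                raise ValueError(f"unconverted C at non-CpG position {i}")


def convert_reference(spec: AmpliconSpec) -> ConvertedReference:
    """In-silico bisulfite conversion: non-CpG C -> T, CpG C kept.

    Idempotent: converting the converted sequence again is a no-op.
    """
    cpg = set(spec.cpg_positions)
    seq = "".join(
        "T" if (b == "C" and i not in cpg) else b
        for i, b in enumerate(spec.reference_seq)
    )
    return ConvertedReference(converted_seq=seq, source=spec)


def build_amplicon_spec(fasta: str | Path, assay_config: str | Path | dict) -> AmpliconSpec:
    """Build a validated :class:`AmpliconSpec` from a FASTA + assay config.

    The FASTA must contain exactly one record.  The config (YAML/JSON-style
    mapping or path to a YAML file) carries keys ``name``, ``cpg_positions``,
    ``control_positions``, ``coordinate_base`` (0 or 1; default 1, i.e.
    positions are taken as printed in assay documentation), ``primer_fwd``,
    ``primer_rev`` and ``barcodes`` (barcode -> sample map).

    Duplicate control positions are deduplicated with a logged warning
    (assay sheets occasionally list a control twice); duplicate CpG
    positions are an error.
    """
    records = list(SeqIO.parse(str(fasta), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, got {len(records)}")
    seq = str(records[0].seq).upper()

    if not isinstance(assay_config, dict):
        with open(assay_config) as fh:
            assay_config = yaml.safe_load(fh)
    cfg = dict(assay_config)
    base = int(cfg.get("coordinate_base", 1))
    if base not in (0, 1):
        raise ValueError("coordinate_base must be 0 or 1")

    cpg = sorted(int(p) - base for p in cfg["cpg_positions"])
    raw_controls = [int(p) - base for p in cfg.get("control_positions", [])]
    controls = sorted(set(raw_controls))
    if len(controls) != len(raw_controls):
        dupes = sorted({p + base for p in raw_controls if raw_controls.count(p) > 1})
        logger.warning(
            "duplicate control position(s) %s in assay config %r; deduplicated",
            dupes, cfg.get("name", "?"),
        )
    return AmpliconSpec(
        name=cfg.get("name", records[0].id),
        reference_seq=seq,
        cpg_positions=tuple(cpg),
        control_positions=tuple(controls),
        barcode_map=dict(cfg.get("barcodes", {})),
        primer_fwd=cfg.get("primer_fwd", ""),
        primer_rev=cfg.get("primer_rev", ""),
    )


# ---------------------------------------------------------------------------
# Default assay used by the simulator and the demo pipeline.
#
# The printed site coordinates of the CpG-island assay (CpG cytosines at
# 1-based positions 2, 4, 6, 18, 22, 37, 40, 51; conversion controls at 14
# and 20) are honoured exactly.  The amplicon sequence itself is a SYNTHETIC
# 62-bp construct (the genomic sequence of the assayed island is not part of
# this package); a synthetic third control at 1-based 44 rounds out the
# usual three-control design.
# ---------------------------------------------------------------------------

DEFAULT_REFERENCE = (
    "ACGCGCGTAT" "GATCATACGC" "ACGTAGATTG" "ATATGACGTC" "GATCTATGAT" "CGTAGATATA" "GT"
)
DEFAULT_CPG_POSITIONS_1BASED = (2, 4, 6, 18, 22, 37, 40, 51)
DEFAULT_CONTROL_POSITIONS_1BASED = (14, 20, 44)


def default_amplicon_spec(barcode_map: Mapping[str, str] | None = None) -> AmpliconSpec:
    """The package's default (synthetic-sequence) 8-CpG assay."""
    return AmpliconSpec(
        name="csx_island_8cpg_synthetic",
        reference_seq=DEFAULT_REFERENCE,
        cpg_positions=tuple(p - 1 for p in DEFAULT_CPG_POSITIONS_1BASED),
        control_positions=tuple(p - 1 for p in DEFAULT_CONTROL_POSITIONS_1BASED),
        barcode_map=dict(barcode_map or {}),
        primer_fwd="GGGGAGAAGGGGTTTTTAATAT",
        primer_rev="AAAAACACTCCTAAAAAAACAACTAA",
    )
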