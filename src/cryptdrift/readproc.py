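"""From barcoded FASTQ reads to per-read methylation pattern calls.

Stages: barcode demultiplexing, bisulfite-aware global alignment against the
in-silico converted reference, full-amplicon coverage filtering, conversion
control filtering (every control cytosine must read T), and per-read CpG
genotyping (C -> M, T -> U).

Two alignment code paths give identical results:

* :func:`align_read` — a plain Needleman–Wunsch global aligner with a
  CpG-tolerant substitution rule (reference C at a CpG site matches read C
  and T), linear gap penalty, full traceback.  Used for single reads and as
  the gapped fallback.
* a batch scorer inside :func:`process_reads` that computes exact global
  alignment scores for an entire read matrix at once (row-wise dynamic
  programming with a running-max unrolling of the horizontal gap chain).
  Reads whose optimal score equals their ungapped score are genotyped
  positionally; the rest fall back to :func:`align_read` traceback.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .amplicon import AmpliconSpec, ConvertedReference

logger = logging.getLogger(__name__)

DISCARD_REASONS = (
    "unassigned_barcode",
    "low_alignment_score",
    "partial_coverage",
    "failed_conversion_control",
    "ambiguous_cpg",
)

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# ---------------------------------------------------------------------------
# FASTQ I/O (minimal 4-line reader/writer; plain or gzip)
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTQ file (.gz supported).

    Raises ``ValueError`` naming the record index on a malformed record.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or len(qual) != len(seq):
                raise ValueError(f"malformed FASTQ record at index {idx} in {path}")
            yield header[1:].split()[0], seq.upper()
            idx += 1


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, str]]) -> int:
    """Write (id, seq, qual) records; returns the number written."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    n = 0
    with opener(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AlignParams:
    """Alignment/filter configuration.

    Scoring is linear-gap Needleman–Wunsch: ``match``/``mismatch`` per
    aligned pair, ``gap`` per gapped position; a read is discarded when its
    optimal score falls below ``score_floor_frac`` x (amplicon length x
    match).  ``coverage_policy`` is ``"strict"`` (every reference position
    must be read-covered) or ``"sites-only"`` (all CpG + control positions
    covered).  Reads whose length differs from the amplicon by more than
    ``length_tolerance`` are discarded as low-score without alignment.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0
    score_floor_frac: float = 0.6
    coverage_policy: str = "strict"
    length_tolerance: int = 10
    max_mismatch_barcode: int = 0
    orient: bool = True

    def score_floor(self, ref_len: int) -> float:
        return self.score_floor_frac * ref_len * self.match


@dataclass
class ReadCall:
    """One read's per-CpG methylation genotype plus its filter fate."""

    read_id: str
    sample_id: str
    pattern: str  # M/U string over CpG sites; "" when discarded
    control_ok: bool
    covers_full_amplicon: bool
    n_ambiguous_sites: int
    alignment_score: float


@dataclass
class FilterLedger:
    """QC accounting: every input read is either passed or counted once
    under a discard reason; conservation is enforced by :meth:`check`."""

    passed: int = 0
    discards: Counter = field(default_factory=Counter)
    total: int = 0

    def discard(self, reason: str, n: int = 1) -> None:
        if reason not in DISCARD_REASONS:
            raise ValueError(f"unknown discard reason {reason!r}")
        self.discards[reason] += n
        self.total += n

    def keep(self, n: int = 1) -> None:
        self.passed += n
        self.total += n

    def check(self) -> None:
        if self.passed + sum(self.discards.values()) != self.total:
            raise AssertionError("filter ledger does not conserve reads")

    def as_dict(self) -> dict[str, int]:
        d = {r: self.discards.get(r, 0) for r in DISCARD_REASONS}
        d["passed"] = self.passed
        d["total"] = self.total
        return d


@dataclass
class Alignment:
    """Global alignment of one read to the converted reference:
    ``ref_bases[i]`` is the read base aligned to reference position i, or
    '-' for a deletion."""

    ref_bases: str
    score: float
    read_is_revcomp: bool = False


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------

def demultiplex(
    reads: Iterable[tuple[str, str]],
    spec: AmpliconSpec,
    max_mismatch: int = 0,
) -> Iterator[tuple[str | None, str, str]]:
    """Assign reads to samples by their 5' barcode; yields
    ``(sample_id | None, read_id, trimmed_seq)``.

    A read matching two barcodes at equal (minimal) mismatch distance is
    left unassigned — never guess.
    """
    bl = spec.barcode_length
    barcodes = list(spec.barcode_map)
    for read_id, seq in reads:
        prefix = seq[:bl]
        if max_mismatch == 0:
            sample = spec.barcode_map.get(prefix)
            yield sample, read_id, seq[bl:]
            continue
        best, best_d, tie = None, max_mismatch + 1, False
        for bc in barcodes:
            d = sum(a != b for a, b in zip(prefix, bc))
            if d < best_d:
                best, best_d, tie = bc, d, False
            elif d == best_d:
                tie = True
        if best is None or tie or len(prefix) < bl:
            yield None, read_id, seq[bl:]
        else:
            yield spec.barcode_map[best], read_id, seq[bl:]


# ---------------------------------------------------------------------------
# Single-read Needleman–Wunsch with traceback (reference implementation)
# ---------------------------------------------------------------------------

def _substitution_row(ref_char: str, is_cpg: bool, read_arr: np.ndarray,
                      params: AlignParams) -> np.ndarray:
    ref_b = ord(ref_char)
    m = read_arr == ref_b
    if is_cpg and ref_char == "C":
        m = m | (read_arr == ord("T"))
    return np.where(m, params.match, params.mismatch)


def align_read(
    read: str,
    ref: ConvertedReference,
    params: AlignParams | None = None,
) -> Alignment:
    """Global (end-to-end) alignment of one read against the converted
    reference with the CpG-tolerant substitution rule.

    Traceback tie-break is deterministic: diagonal, then gap-in-read
    (deletion), then gap-in-reference (insertion).
    """
    params = params or AlignParams()
    refseq = ref.converted_seq
    cpg = set(ref.source.cpg_positions)
    m, L = len(refseq), len(read)
    read_arr = np.frombuffer(read.encode(), dtype=np.uint8)
    g = params.gap

    H = np.empty((m + 1, L + 1), dtype=np.float64)
    H[0, :] = g * np.arange(L + 1)
    H[:, 0] = g * np.arange(m + 1)
    for i in range(1, m + 1):
        sub = _substitution_row(refseq[i - 1], (i - 1) in cpg, read_arr, params)
        diag = H[i - 1, :-1] + sub
        up = H[i - 1, 1:] + g
        Mrow = np.maximum(diag, up)
        # unroll horizontal gap chain: H[i, j] = g*j + cummax(M - g*k)
        B = np.empty(L + 1)
        B[0] = H[i, 0]
        B[1:] = Mrow - g * np.arange(1, L + 1)
        np.maximum.accumulate(B, out=B)
        H[i, 1:] = B[1:] + g * np.arange(1, L + 1)
        H[i, 0] = g * i

    # traceback
    out = ["-"] * m
    i, j = m, L
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            sub = _substitution_row(refseq[i - 1], (i - 1) in cpg,
                                    read_arr[j - 1:j], params)[0]
            if np.isclose(H[i, j], H[i - 1, j - 1] + sub):
                out[i - 1] = read[j - 1]
                i, j = i - 1, j - 1
                continue
        if i > 0 and np.isclose(H[i, j], H[i - 1, j] + g):
            out[i - 1] = "-"
            i -= 1
            continue
        j -= 1  # insertion in read
    return Alignment(ref_bases="".join(out), score=float(H[m, L]))


def orient_read(read: str, ref: ConvertedReference,
                params: AlignParams | None = None) -> tuple[str, bool]:
    """Return the read in amplicon orientation (best-of forward vs
    reverse-complement alignment score; ties keep forward)."""
    params = params or AlignParams()
    fwd = align_read(read, ref, params).score
    rc = reverse_complement(read)
    rev = align_read(rc, ref, params).score
    return (rc, True) if rev > fwd else (read, False)


# ---------------------------------------------------------------------------
# Filters and genotyping on an Alignment
# ---------------------------------------------------------------------------

def apply_coverage_filter(aln: Alignment, spec: AmpliconSpec,
                          policy: str = "strict") -> bool:
    """True iff the read fully covers the amplicon under the given policy."""
    if policy == "strict":
        return "-" not in aln.ref_bases
    if policy == "sites-only":
        sites = list(spec.cpg_positions) + list(spec.control_positions)
        return all(aln.ref_bases[p] != "-" for p in sites)
    raise ValueError(f"unknown coverage policy {policy!r}")


def check_conversion_controls(aln: Alignment, spec: AmpliconSpec) -> bool:
    """True iff every control cytosine reads T (perfect conversion).

    A C marks incomplete bisulfite conversion; any other base is a
    sequencing artefact — both invalidate the read.
    """
    return all(aln.ref_bases[p] == "T" for p in spec.control_positions)


def genotype_cpgs(aln: Alignment, spec: AmpliconSpec, read_id: str = "",
                  sample_id: str = "") -> ReadCall:
    """Genotype each CpG site in the context of the single read:
    C -> M (methylated), T -> U (unmethylated), anything else ambiguous."""
    calls = []
    n_amb = 0
    for p in spec.cpg_positions:
        b = aln.ref_bases[p]
        if b == "C":
            calls.append("M")
        elif b == "T":
            calls.append("U")
        else:
            calls.append("?")
            n_amb += 1
    return ReadCall(
        read_id=read_id,
        sample_id=sample_id,
        pattern="" if n_amb else "".join(calls),
        control_ok=check_conversion_controls(aln, spec),
        covers_full_amplicon="-" not in aln.ref_bases,
        n_ambiguous_sites=n_amb,
        alignment_score=aln.score,
    )


# ---------------------------------------------------------------------------
# Vectorized batch engine
# ---------------------------------------------------------------------------

def _batch_nw_scores(reads: np.ndarray, refseq: str, cpg: Sequence[int],
                     params: AlignParams) -> np.ndarray:
    """Exact global-alignment scores for a (n_reads, read_len) uint8 matrix.

    Same recurrence as :func:`align_read`, iterated over reference rows and
    vectorized across reads; the horizontal gap chain is unrolled with a
    running maximum (valid for linear gap penalties).
    """
    n, L = reads.shape
    m = len(refseq)
    g = params.gap
    cpgset = set(cpg)
    jg = g * np.arange(L + 1, dtype=np.float32)
    Hprev = np.broadcast_to(jg, (n, L + 1)).copy()
    H = np.empty_like(Hprev)
    T_b = ord("T")
    for i in range(1, m + 1):
        ref_b = ord(refseq[i - 1])
        match = reads == ref_b
        if (i - 1) in cpgset and refseq[i - 1] == "C":
            match = match | (reads == T_b)
        sub = np.where(match, params.match, params.mismatch).astype(np.float32)
        B = np.empty_like(Hprev)
        B[:, 0] = g * i
        np.maximum(Hprev[:, :-1] + sub, Hprev[:, 1:] + g, out=B[:, 1:])
        B -= jg
        np.maximum.accumulate(B, axis=1, out=B)
        np.add(B, jg, out=H)
        H[:, 0] = g * i
        Hprev, H = H, Hprev
    return Hprev[:, -1].astype(np.float64)


def _encode(seqs: list[str]) -> np.ndarray:
    return (np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
            .reshape(len(seqs), -1).copy())


def process_reads(
    reads: Iterable[tuple[str, str]],
    spec: AmpliconSpec,
    ref: ConvertedReference,
    params: AlignParams | None = None,
) -> tuple[pd.DataFrame, FilterLedger, pd.DataFrame]:
    """Run demultiplex -> orient/align -> filter -> genotype over a read
    stream.

    Returns ``(calls, ledger, per_sample_ledger)`` where ``calls`` has one
    row per passed read (read_id, sample_id, pattern, alignment_score) and
    ``per_sample_ledger`` counts reads per sample per fate.
    """
    params = params or AlignParams()
    refseq = ref.converted_seq
    m = len(refseq)
    cpg = list(spec.cpg_positions)
    controls = list(spec.control_positions)
    floor = params.score_floor(m)
    ledger = FilterLedger()
    per_sample: Counter = Counter()

    by_len: dict[int, list[tuple[str, str, str]]] = {}
    n_in = 0
    for sample, read_id, seq in demultiplex(reads, spec, params.max_mismatch_barcode):
        n_in += 1
        if n_in % 100_000 == 0:
            logger.info("demultiplexed %d reads", n_in)
        if sample is None:
            ledger.discard("unassigned_barcode")
            per_sample[("<unassigned>", "unassigned_barcode")] += 1
            continue
        by_len.setdefault(len(seq), []).append((sample, read_id, seq))

    rows: list[tuple[str, str, str, float]] = []
    for L, group in sorted(by_len.items()):
        samples = [g[0] for g in group]
        ids = [g[1] for g in group]
        seqs = [g[2] for g in group]
        if abs(L - m) > params.length_tolerance or L == 0:
            ledger.discard("low_alignment_score", len(group))
            for s in samples:
                per_sample[(s, "low_alignment_score")] += 1
            continue
        arr = _encode(seqs)
        scores = _batch_nw_scores(arr, refseq, cpg, params)
        if params.orient:
            rc = arr[:, ::-1].copy()
            for a, b in ((ord("A"), ord("T")), (ord("C"), ord("G"))):
                mask_a, mask_b = rc == a, rc == b
                rc[mask_a], rc[mask_b] = b, a
            rc_scores = _batch_nw_scores(rc, refseq, cpg, params)
            flip = rc_scores > scores
            if flip.any():
                arr[flip] = rc[flip]
                scores = np.where(flip, rc_scores, scores)

        if L == m:
            # ungapped positional score; equal to NW score => positional
            # genotyping is an optimal alignment (preferred tie-break)
            match = arr == np.frombuffer(refseq.encode(), np.uint8)
            cpg_tol = np.zeros(m, bool)
            cpg_tol[cpg] = True
            match |= cpg_tol & (arr == ord("T"))
            s0 = np.where(match, params.match, params.mismatch).sum(axis=1)
            exact = s0 == scores
        else:
            exact = np.zeros(len(group), bool)

        for k in range(len(group)):
            s, rid = samples[k], ids[k]
            score = float(scores[k])
            if score < floor:
                ledger.discard("low_alignment_score")
                per_sample[(s, "low_alignment_score")] += 1
                continue
            if exact[k]:
                bases = arr[k].tobytes().decode()
                covered = True
            else:
                aln = align_read(arr[k].tobytes().decode(), ref, params)
                bases = aln.ref_bases
                covered = apply_coverage_filter(aln, spec, params.coverage_policy)
            if not covered:
                ledger.discard("partial_coverage")
                per_sample[(s, "partial_coverage")] += 1
                continue
            if any(bases[p] != "T" for p in controls):
                ledger.discard("failed_conversion_control")
                per_sample[(s, "failed_conversion_control")] += 1
                continue
            pattern = []
            ok = True
            for p in cpg:
                b = bases[p]
                if b == "C":
                    pattern.append("M")
                elif b == "T":
                    pattern.append("U")
                else:
                    ok = False
                    break
            if not ok:
                ledger.discard("ambiguous_cpg")
                per_sample[(s, "ambiguous_cpg")] += 1
                continue
            ledger.keep()
            per_sample[(s, "passed")] += 1
            rows.append((rid, s, "".join(pattern), score))

    ledger.check()
    calls = pd.DataFrame(rows, columns=["read_id", "sample_id", "pattern", "alignment_score"])
    ps = pd.DataFrame(
        [(s, fate, n) for (s, fate), n in sorted(per_sample.items())],
        columns=["sample_id", "fate", "n_reads"],
    )
    return calls, ledger, ps
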