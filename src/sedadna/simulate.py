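"""Simulation of sediment ancient-DNA sequencing reads with ground truth.

The generator reproduces the statistical structure that the screening
pipeline keys on, each feature with an explicit, recoverable parameter:

* short fragments — gamma-distributed lengths truncated to [35, 100] bp
  with a truncated mean of ~42 bp;
* cytosine deamination — C->T flips at rate ``d_bg + d_max*exp(-lambda*i)``
  where ``i`` is the 0-based distance from the nearer read end, applied at
  both ends in read orientation (single-stranded library chemistry; a
  double-stranded mode puts C->T at 5' and G->A at 3' only);
* depurination — fragment breakpoints preferentially fall immediately
  downstream of purines, with configurable odds weight;
* PCR duplicates — each molecule is emitted 1 + Poisson(dup_mean) times;
* modern contamination — a configurable fraction of reads drawn
  undamaged, and longer, from a contaminant reference.

Every read gets a ground-truth row (source, interval, strand, damaged and
error positions, duplicate provenance), a FASTQ record, and a perfect SAM
alignment at its generating coordinates — so each downstream stage can be
tested against known truth without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .damage import DamageProfile
from .fragments import AlignedFragment, Fragment, PURINES, revcomp

_BASES = np.array(list("ACGT"))


@dataclass
class SimParams:
    """Knobs of the ancient-read generator; defaults emulate the screening
    study's observed fragment structure."""

    seed: int = 0
    n_fragments: int = 1000
    length_shape: float = 21.0
    length_scale: float = 1.75
    min_len: int = 35
    max_len: int = 100
    d_max: float = 0.4
    decay: float = 0.3  # per-position exponential decay rate of deamination
    d_bg: float = 0.01
    purine_break_weight: float = 3.0
    seq_error: float = 0.001
    dup_mean: float = 0.5
    contam_fraction: float = 0.2
    contam_reference: Optional[str] = None
    contam_length_scale: float = 3.0
    contam_max_len: int = 150
    taxon_mix: dict[str, float] = field(default_factory=dict)
    single_stranded: bool = True
    read_group: str = "sim"
    library_id: str = "simlib"

    def __post_init__(self) -> None:
        for name in ("d_max", "d_bg", "seq_error", "contam_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.purine_break_weight < 1.0:
            raise ValueError("purine_break_weight must be >= 1")
        if self.taxon_mix:
            total = sum(self.taxon_mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"taxon_mix proportions sum to {total}, not 1")


def generate_reference(length: int, gc_fraction: float, seed: int) -> str:
    """A reproducible random circular reference with expected GC content."""
    if length < 1000:
        raise ValueError("reference length must be >= 1000")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    return "".join(rng.choice(_BASES, size=length, p=p))


@dataclass
class SimResult:
    """Reads, ground truth, and perfect alignments from one simulation."""

    fragments: list[Fragment]
    truth: pd.DataFrame
    alignments: list[AlignedFragment]


TRUTH_COLUMNS = [
    "read_id", "source", "ref_start", "ref_end", "strand", "length",
    "is_contaminant", "wrapped", "deaminated_positions", "error_positions",
    "duplicate_of",
]


def _sample_length(rng, shape, scale, lo, hi) -> int:
    for _ in range(100_000):
        x = int(round(rng.gamma(shape, scale)))
        if lo <= x <= hi:
            return x
    raise RuntimeError("length model rejects everything in [min_len, max_len]")


def _circular_slice(ref: str, start: int, length: int) -> str:
    L = len(ref)
    start %= L
    if start + length <= L:
        return ref[start : start + length]
    return ref[start:] + ref[: start + length - L]


def _sample_interval(rng, ref: str, length: int, strand: str, w: float) -> int:
    """Start of a circular interval, rejection-sampled for purine flanks.

    A candidate placement is accepted with probability 1 if the base
    immediately upstream of the read's 5' end (in read orientation) is a
    purine, else 1/w — and independently for the base immediately
    downstream of the 3' end.  This realises odds ``w : 1`` for a purine
    at each breakpoint flank.
    """
    L = len(ref)
    while True:
        s = int(rng.integers(L))
        up = ref[(s - 1) % L]
        down = ref[(s + length) % L]
        if strand == "+":
            b5, b3 = up, down
        else:
            # read orientation flips: 5' flank is the complement of the
            # base after the interval, 3' flank the complement of the one
            # before it; complementation preserves purine-ness' negation,
            # so test the complements.
            b5 = _COMP[down]
            b3 = _COMP[up]
        acc = 1.0
        if b5 not in PURINES:
            acc /= w
        if b3 not in PURINES:
            acc /= w
        if acc >= 1.0 or rng.random() < acc:
            return s


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _apply_damage(rng, seq: str, params: SimParams) -> tuple[str, list[int]]:
    """Deaminate in read orientation; returns new sequence + flip positions."""
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype="S1")
    i = np.arange(n, dtype=float)
    draws = rng.random(n)
    out = arr.copy()
    if params.single_stranded:
        d = np.minimum(i, n - 1 - i)
        p = params.d_bg + params.d_max * np.exp(-params.decay * d)
        flip = (arr == b"C") & (draws < p)
        out[flip] = b"T"
    else:
        p5 = params.d_bg + params.d_max * np.exp(-params.decay * i)
        p3 = params.d_bg + params.d_max * np.exp(-params.decay * (n - 1 - i))
        flip_c = (arr == b"C") & (draws < p5)
        flip_g = (arr == b"G") & (draws < p3)
        out[flip_c] = b"T"
        out[flip_g] = b"A"
        flip = flip_c | flip_g
    return out.tobytes().decode(), np.flatnonzero(flip).tolist()


_ERROR_TARGETS = {b: [c for c in "ACGT" if c != b] for b in "ACGTN"}
_ERROR_TARGETS["N"] = ["A", "C", "G"]


def _apply_errors(rng, seq: str, rate: float) -> tuple[str, list[int]]:
    n = len(seq)
    draws = rng.random(n)
    hit = np.flatnonzero(draws < rate)
    if hit.size == 0:
        return seq, []
    out = list(seq)
    offs = rng.integers(3, size=hit.size)
    for pos, off in zip(hit.tolist(), offs.tolist()):
        out[pos] = _ERROR_TARGETS[out[pos]][off]
    return "".join(out), hit.tolist()


def simulate_fragments(
    params: SimParams, references: dict[str, str]
) -> SimResult:
    """Generate reads, truth rows and perfect alignments.

    ``references`` maps reference id to (circular) sequence; sources are
    drawn from ``params.taxon_mix`` (uniform over non-contaminant
    references when the mix is empty), or from ``params.contam_reference``
    with probability ``params.contam_fraction``.  Fragments wrapping the
    circular origin are split into two alignment records and flagged in
    the truth table.  Output is byte-deterministic for a fixed seed.
    """
    if not references:
        raise ValueError("empty reference set")
    rng = np.random.default_rng(params.seed)
    if params.contam_fraction > 0 and params.contam_reference is None:
        raise ValueError("contam_fraction > 0 requires contam_reference")
    if params.taxon_mix:
        mix_ids = sorted(params.taxon_mix)
        mix_p = np.array([params.taxon_mix[t] for t in mix_ids])
    else:
        mix_ids = sorted(r for r in references if r != params.contam_reference)
        if not mix_ids:
            raise ValueError("no non-contaminant references to sample from")
        mix_p = np.full(len(mix_ids), 1.0 / len(mix_ids))
    for t in mix_ids:
        if t not in references:
            raise ValueError(f"taxon_mix reference {t!r} not supplied")

    fragments: list[Fragment] = []
    alignments: list[AlignedFragment] = []
    truth_rows: list[dict] = []

    for r in range(params.n_fragments):
        contam = (
            params.contam_fraction > 0 and rng.random() < params.contam_fraction
        )
        if contam:
            src = params.contam_reference
            length = _sample_length(
                rng, params.length_shape, params.contam_length_scale,
                params.min_len, params.contam_max_len,
            )
        else:
            src = mix_ids[int(rng.choice(len(mix_ids), p=mix_p))]
            length = _sample_length(
                rng, params.length_shape, params.length_scale,
                params.min_len, params.max_len,
            )
        ref = references[src]
        strand = "+" if rng.random() < 0.5 else "-"
        start = _sample_interval(rng, ref, length, strand, params.purine_break_weight)
        template = _circular_slice(ref, start, length)
        read_seq = template if strand == "+" else revcomp(template)
        if contam:
            damaged, deam_pos = read_seq, []
        else:
            damaged, deam_pos = _apply_damage(rng, read_seq, params)
        final, err_pos = _apply_errors(rng, damaged, params.seq_error)

        n_copies = 1 + int(rng.poisson(params.dup_mean))
        base_id = f"read{r:06d}"
        wrapped = start + length > len(ref)
        for c in range(n_copies):
            rid = base_id if c == 0 else f"{base_id}.dup{c}"
            fragments.append(
                Fragment(id=rid, sequence=final, library_id=params.library_id)
            )
            truth_rows.append(
                {
                    "read_id": rid,
                    "source": src,
                    "ref_start": start,
                    "ref_end": start + length,
                    "strand": strand,
                    "length": length,
                    "is_contaminant": contam,
                    "wrapped": wrapped,
                    "deaminated_positions": ",".join(map(str, deam_pos)),
                    "error_positions": ",".join(map(str, err_pos)),
                    "duplicate_of": "" if c == 0 else base_id,
                }
            )
            alignments.extend(
                _perfect_alignments(
                    rid, src, len(ref), start, length, strand, final,
                    params.library_id,
                )
            )

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return SimResult(fragments=fragments, truth=truth, alignments=alignments)


def _perfect_alignments(
    read_id, ref_id, ref_len, start, length, strand, read_seq, library_id
) -> list[AlignedFragment]:
    """Perfect (gapless, MQ 37) alignment records; wrapped fragments split
    into two records covering the two linear pieces."""
    sam_seq = read_seq if strand == "+" else revcomp(read_seq)
    pieces: list[tuple[int, int, int]] = []  # (ref_start, ref_end, sam_seq offset)
    if start + length <= ref_len:
        pieces.append((start, start + length, 0))
    else:
        first = ref_len - start
        pieces.append((start, ref_len, 0))
        pieces.append((0, length - first, first))
    out = []
    for idx, (rs, re_, off) in enumerate(pieces):
        pairs = [
            (rs + j, off + j, sam_seq[off + j]) for j in range(re_ - rs)
        ]
        out.append(
            AlignedFragment(
                fragment_id=read_id if idx == 0 else f"{read_id}/wrap",
                reference_id=ref_id,
                ref_start=rs,
                ref_end=re_,
                strand=strand,
                mapping_quality=37,
                pairs=pairs,
                library_id=library_id,
            )
        )
    return out


def fit_damage_decay(profile: DamageProfile) -> tuple[float, float, float, float]:
    """Recover (d_max, lambda, d_bg) from a C->T substitution profile.

    Fits ``f(i) = d_bg + d_max * exp(-lambda * i)`` (``i`` = 0-based
    position from the end) to the pooled 5'+3' per-position C->T
    frequencies by weighted least squares, weights proportional to the
    position denominators.  Returns ``(d_max, lambda, d_bg, rss)``.

    Raises
    ------
    ValueError
        Fewer than 3 positions with nonzero denominators, or window < 5.
    """
    if profile.window < 5:
        raise ValueError("profile window must be >= 5 for a decay fit")
    k5, n5 = profile.ct_series(0)
    k3, n3 = profile.ct_series(1)
    k, n = k5 + k3, n5 + n3
    ok = n > 0
    if ok.sum() < 3:
        raise ValueError("need nonzero denominators at >= 3 positions")
    x = np.arange(profile.window, dtype=float)[ok]
    f = (k[ok] / n[ok]).astype(float)
    w = n[ok].astype(float)

    def model(i, d_max, lam, d_bg):
        return d_bg + d_max * np.exp(-lam * i)

    f_tail = float(f[-1])
    p0 = (max(float(f[0]) - f_tail, 1e-3), 0.3, max(f_tail, 1e-6))
    popt, _ = curve_fit(
        model, x, f, p0=p0,
        sigma=1.0 / np.sqrt(w),
        bounds=([0.0, 1e-6, 0.0], [1.0, 10.0, 1.0]),
        maxfev=20000,
    )
    rss = float(np.sum(w * (f - model(x, *popt)) ** 2))
    d_max, lam, d_bg = map(float, popt)
    return d_max, lam, d_bg, rss
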