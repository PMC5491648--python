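"""Clonal bisulfite-sequencing methylation analysis.

Designed for Sanger-scale amplicon data: a reference region (unconverted
genomic top strand) plus ~10 bisulfite-converted clone sequences per sample.
Pipeline: bisulfite-aware global alignment (C→T collapsed scoring) →
per-reference-cytosine methylation calls with CG/CHG/CHH context → per-context
5mC summaries → sliding-window Fisher-exact DMR tests (default 100-bp windows,
50-bp step, two-sided p ≤ 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from saltphen.stats import fisher_exact_2x2

__all__ = [
    "ReferenceRegion",
    "CloneSet",
    "CloneAlignment",
    "MethylationSummary",
    "WindowTest",
    "LowIdentityError",
    "align_clone",
    "align_clones",
    "classify_context",
    "call_methylation",
    "summarize_context",
    "call_dmrs",
]

logger = logging.getLogger(__name__)

DNA_ALPHABET = set("ACGTN")
CONTEXTS = ("CG", "CHG", "CHH")
H_BASES = set("ACT")


class LowIdentityError(ValueError):
    """Clone rejected: collapsed-alignment identity below the floor."""


@dataclass(frozen=True)
class ReferenceRegion:
    """Reference amplicon: unconverted genomic top-strand sequence.

    ``offset`` is the 0-based start of the region within the gene body, so
    reported coordinates can be anchored on the gene.
    """

    region_id: str
    sequence: str
    offset: int = 0

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError("reference sequence is empty")
        if set(seq) - DNA_ALPHABET:
            raise ValueError("reference contains non-ACGTN characters")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CloneSet:
    """Bisulfite clone reads for one (genotype, tissue, treatment) sample."""

    genotype: str
    tissue: str
    treatment: str
    clones: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.clones:
            raise ValueError("clone set is empty")
        object.__setattr__(
            self, "clones", tuple(c.upper() for c in self.clones)
        )

    @property
    def sample_key(self) -> tuple[str, str, str]:
        return (self.genotype, self.tissue, self.treatment)


@dataclass(frozen=True)
class CloneAlignment:
    """Global alignment of one clone to the reference (original bases)."""

    ref_aligned: str
    clone_aligned: str
    score: float
    identity: float  # fraction of matching columns on the C→T collapsed pair


@dataclass
class MethylationSummary:
    """Methylated / unmethylated call counts per context plus the pooled total."""

    counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def percent(self, context: str = "total") -> Optional[float]:
        m, u = self.counts.get(context, (0, 0))
        if m + u == 0:
            return None  # no informative calls: undefined, not 0
        return 100.0 * m / (m + u)

    @property
    def total(self) -> tuple[int, int]:
        return self.counts.get("total", (0, 0))


@dataclass(frozen=True)
class WindowTest:
    """Fisher 2×2 result for one reference window (0-based half-open)."""

    start: int
    end: int
    meth_a: int
    unmeth_a: int
    meth_b: int
    unmeth_b: int
    p_value: float
    direction: Optional[str]  # 'hyper'/'hypo' in A relative to B
    is_dmr: bool

    @property
    def frac_a(self) -> float:
        return self.meth_a / (self.meth_a + self.unmeth_a)

    @property
    def frac_b(self) -> float:
        return self.meth_b / (self.meth_b + self.unmeth_b)


def _collapse(seq: str) -> str:
    """Three-letter bisulfite collapse: every C becomes T."""
    return seq.replace("C", "T")


def _gotoh_align(
    a: str,
    b: str,
    match: float,
    mismatch: float,
    gap_open: float,
    gap_extend: float,
) -> tuple[float, str, str]:
    """Global affine-gap alignment (Gotoh) with deterministic tie-breaking.

    A gap run of length k costs gap_open + (k-1)*gap_extend.  Traceback
    prefers diagonal, then up (gap in b), then left (gap in a).
    Returns (score, gapped_a, gapped_b).
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # ends with gap in b (up)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # ends with gap in a (left)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        ai = a[i - 1]
        Mi, Mp = M[i], M[i - 1]
        Xi, Xp = X[i], X[i - 1]
        Yi, Yp = Y[i], Y[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            Mi[j] = max(Mp[j - 1], Xp[j - 1], Yp[j - 1]) + s
            Xi[j] = max(Mp[j] + gap_open, Xp[j] + gap_extend, Yp[j] + gap_open)
            Yi[j] = max(Mi[j - 1] + gap_open, Yi[j - 1] + gap_extend, Xi[j - 1] + gap_open)

    i, j = n, m
    score = max(M[n][m], X[n][m], Y[n][m])
    # state priority encodes the tie-break: diagonal, then up, then left
    if M[i][j] == score:
        state = "M"
    elif X[i][j] == score:
        state = "X"
    else:
        state = "Y"
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            s = match if a[i - 1] == b[j - 1] else mismatch
            target = M[i][j] - s
            i, j = i - 1, j - 1
            state = (
                "M" if M[i][j] == target else ("X" if X[i][j] == target else "Y")
            )
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append("-")
            target = X[i][j]
            i -= 1
            if i == 0 and j == 0:
                break
            if M[i][j] + gap_open == target:
                state = "M"
            elif X[i][j] + gap_extend == target:
                state = "X"
            else:
                state = "Y"
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            target = Y[i][j]
            j -= 1
            if i == 0 and j == 0:
                break
            if M[i][j] + gap_open == target:
                state = "M"
            elif Y[i][j] + gap_extend == target:
                state = "Y"
            else:
                state = "X"
    return score, "".join(reversed(out_a)), "".join(reversed(out_b))


def align_clone(
    reference: str,
    clone: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
    min_identity: float = 0.8,
) -> CloneAlignment:
    """Bisulfite-aware global alignment of a clone to the reference.

    Both sequences are C→T collapsed before scoring so bisulfite conversion is
    never penalized; the original bases are restored in the returned
    alignment.  A collapsed identity below ``min_identity`` rejects the clone
    (:class:`LowIdentityError`).
    """
    ref = reference.upper()
    cln = clone.upper()
    if not ref or not cln:
        raise ValueError("sequences must be non-empty")
    ref_c, cln_c = _collapse(ref), _collapse(cln)

    if ref_c == cln_c:  # gapless: conversion is invisible after collapsing
        return CloneAlignment(ref, cln, match * len(ref), 1.0)

    score, ga, gb = _gotoh_align(ref_c, cln_c, match, mismatch, gap_open, gap_extend)
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    identity = matches / len(ga)
    if identity < min_identity:
        raise LowIdentityError(
            f"collapsed identity {identity:.2%} below floor {min_identity:.0%}"
        )
    # restore original bases onto the gap pattern
    it_a, it_b = iter(ref), iter(cln)
    orig_a = "".join(next(it_a) if x != "-" else "-" for x in ga)
    orig_b = "".join(next(it_b) if y != "-" else "-" for y in gb)
    return CloneAlignment(orig_a, orig_b, score, identity)


def align_clones(
    reference: ReferenceRegion | str, clones: Iterable[str], **kwargs
) -> list[CloneAlignment]:
    """Align every clone, skipping (with a warning log) low-identity rejects."""
    ref = reference.sequence if isinstance(reference, ReferenceRegion) else reference
    out = []
    for idx, clone in enumerate(clones):
        try:
            out.append(align_clone(ref, clone, **kwargs))
        except LowIdentityError as exc:
            logger.warning("clone %d rejected: %s", idx, exc)
    return out


def classify_context(reference: str, pos: int) -> str:
    """Cytosine context at ``pos``: CG, CHG, CHH (H = A/C/T) or unknown.

    'unknown' covers cytosines with fewer than two downstream bases or an N
    in the lookahead.
    """
    seq = reference.upper() if not reference.isupper() else reference
    if seq[pos] != "C":
        raise ValueError(f"reference base at {pos} is {seq[pos]!r}, not C")
    if pos + 1 >= len(seq):
        return "unknown"
    b1 = seq[pos + 1]
    if b1 == "G":
        return "CG"
    if b1 == "N":
        return "unknown"
    if pos + 2 >= len(seq):
        return "unknown"
    b2 = seq[pos + 2]
    if b2 == "N":
        return "unknown"
    if b1 in H_BASES and b2 == "G":
        return "CHG"
    if b1 in H_BASES and b2 in H_BASES:
        return "CHH"
    return "unknown"


def reference_contexts(reference: str) -> dict[int, str]:
    """Context of every cytosine position in the reference (pure function)."""
    return {
        i: classify_context(reference, i)
        for i, base in enumerate(reference.upper())
        if base == "C"
    }


def call_methylation(
    reference: ReferenceRegion | str, alignments: Sequence[CloneAlignment]
) -> pd.DataFrame:
    """Per-(reference C, clone) methylation calls.

    At each reference-cytosine column: clone base C → methylated, T →
    unmethylated, anything else (gap, A, G, N) → ambiguous.  Returns a tidy
    DataFrame with columns ``pos, clone, context, state``.
    """
    ref = reference.sequence if isinstance(reference, ReferenceRegion) else reference.upper()
    contexts = reference_contexts(ref)
    rows = []
    for clone_idx, aln in enumerate(alignments):
        ref_pos = 0
        for col_ref, col_clone in zip(aln.ref_aligned, aln.clone_aligned):
            if col_ref == "-":
                continue  # insertion in the clone: no reference coordinate
            if col_ref == "C":
                if col_clone == "C":
                    state = "methylated"
                elif col_clone == "T":
                    state = "unmethylated"
                else:
                    state = "ambiguous"
                rows.append((ref_pos, clone_idx, contexts[ref_pos], state))
            ref_pos += 1
    return pd.DataFrame(rows, columns=["pos", "clone", "context", "state"])


def summarize_context(calls: pd.DataFrame) -> MethylationSummary:
    """Per-context and total 5mC percentages (ambiguous calls excluded)."""
    informative = calls[calls["state"] != "ambiguous"]
    if informative.empty:
        raise ValueError("no informative methylation calls")
    counts: dict[str, tuple[int, int]] = {}
    for ctx, sub in informative.groupby("context"):
        m = int((sub["state"] == "methylated").sum())
        counts[str(ctx)] = (m, len(sub) - m)
    m_tot = int((informative["state"] == "methylated").sum())
    counts["total"] = (m_tot, len(informative) - m_tot)
    return MethylationSummary(counts)


def _window_counts(calls: pd.DataFrame, start: int, end: int) -> tuple[int, int]:
    sub = calls[
        (calls["pos"] >= start)
        & (calls["pos"] < end)
        & (calls["state"] != "ambiguous")
    ]
    m = int((sub["state"] == "methylated").sum())
    return m, len(sub) - m


def call_dmrs(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    region_length: int,
    window: int = 100,
    step: int = 50,
    alpha: float = 0.05,
    contexts: Optional[Sequence[str]] = None,
) -> list[WindowTest]:
    """Sliding-window Fisher-exact differential-methylation tests.

    Windows [k*step, k*step + window) tile the reference; a trailing short
    window is tested when informative.  Counts pool clones and (by default)
    contexts within each window.  A window is flagged as a DMR iff the
    two-sided p ≤ alpha; direction is the sign of the methylation-fraction
    difference (A − B).  Windows lacking informative calls in either sample
    are skipped with a log entry.  Pass ``contexts`` to restrict to a subset
    (e.g. ``["CG"]``) instead of pooling all.
    """
    if window <= 0 or step <= 0 or step > window:
        raise ValueError("require window > 0 and 0 < step <= window")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if contexts is not None:
        calls_a = calls_a[calls_a["context"].isin(contexts)]
        calls_b = calls_b[calls_b["context"].isin(contexts)]
    tests: list[WindowTest] = []
    for start in range(0, region_length, step):
        end = min(start + window, region_length)
        m_a, u_a = _window_counts(calls_a, start, end)
        m_b, u_b = _window_counts(calls_b, start, end)
        if m_a + u_a == 0 or m_b + u_b == 0:
            logger.info(
                "window [%d, %d): no informative calls in one sample, skipped",
                start,
                end,
            )
            continue
        p = fisher_exact_2x2(m_a, u_a, m_b, u_b)
        fa, fb = m_a / (m_a + u_a), m_b / (m_b + u_b)
        direction = "hyper" if fa > fb else ("hypo" if fa < fb else None)
        tests.append(WindowTest(start, end, m_a, u_a, m_b, u_b, p, direction, p <= alpha))
    return tests
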