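"""qPCR relative expression (ΔΔCt) and pairwise sequence-variant analysis.

Fold changes follow the classic ΔΔCt scheme with amplification efficiency
fixed at 2: technical replicates are averaged per biological replicate,
ΔCt = Ct(target) − Ct(reference) per biological replicate,
ΔΔCt = mean ΔCt(treated) − mean ΔCt(control), ratio = 2^(−ΔΔCt).
Downregulation is reported as an x-fold decrease (reported_fold = 1/ratio),
so the reported fold is always ≥ 1 with an explicit direction.

Variant analysis operates on pre-aligned nucleotide pairs (equal-length,
gapped): substitutions are split into transitions (purine↔purine,
pyrimidine↔pyrimidine) and transversions; a maximal contiguous gap run in one
sequence counts as a single deletion event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "FoldChange",
    "MutationSummary",
    "MotifHit",
    "delta_delta_ct",
    "classify_mutations",
    "translate_cds",
    "find_motifs",
]

CT_COLUMNS = ("genotype", "tissue", "treatment", "gene_name", "bio_rep", "tech_rep", "ct")
PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
NUCLEOTIDES = PURINES | PYRIMIDINES
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY*X")


@dataclass(frozen=True)
class FoldChange:
    gene_name: str
    genotype: str
    tissue: str
    ratio: float  # 2^(-ΔΔCt)
    direction: str  # 'up' | 'down'
    reported_fold: float  # ratio if up, 1/ratio if down; always >= 1
    sd_ddct: float  # SD of per-biological-replicate ΔΔCt
    n_bio: int

    @property
    def fold_range(self) -> tuple[float, float]:
        """Expression-ratio range at ±1 SD of ΔΔCt."""
        return (self.ratio * 2.0**-self.sd_ddct, self.ratio * 2.0**self.sd_ddct)


@dataclass(frozen=True)
class MutationSummary:
    deletion_events: int  # maximal gap runs in seq_b (bases lost from b)
    deleted_bases: int
    insertion_events: int  # gap runs in seq_a
    inserted_bases: int
    transitions: int
    transversions: int
    identities: int
    excluded: int  # N-containing columns
    substitutions: tuple[tuple[int, str, str], ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class MotifHit:
    motif: str
    positions: tuple[int, ...]
    present: bool


def _mean_ct_per_bio_rep(sub: pd.DataFrame) -> pd.Series:
    """Average technical replicates within each biological replicate."""
    return sub.groupby("bio_rep")["ct"].mean()


def delta_delta_ct(
    records: pd.DataFrame,
    gene_name: str,
    genotype: str,
    tissue: str,
    reference_gene: str = "actin",
    control: str = "control",
    treated: str = "salt",
) -> FoldChange:
    """Relative expression of ``gene_name`` in treated vs control samples.

    ``records`` is a tidy Ct table with columns
    ``genotype, tissue, treatment, gene_name, bio_rep, tech_rep, ct``.
    """
    missing = [c for c in CT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if (records["ct"] <= 0).any():
        raise ValueError("Ct values must be > 0")
    cell = records[(records["genotype"] == genotype) & (records["tissue"] == tissue)]
    dct = {}
    for condition in (control, treated):
        sub = cell[cell["treatment"] == condition]
        tgt = sub[sub["gene_name"] == gene_name]
        ref = sub[sub["gene_name"] == reference_gene]
        if tgt.empty:
            raise ValueError(
                f"no {gene_name!r} Ct values for {genotype}/{tissue}/{condition}"
            )
        if ref.empty:
            raise ValueError(
                f"reference gene {reference_gene!r} missing for "
                f"{genotype}/{tissue}/{condition}"
            )
        tgt_ct = _mean_ct_per_bio_rep(tgt)
        ref_ct = _mean_ct_per_bio_rep(ref)
        if set(tgt_ct.index) != set(ref_ct.index):
            raise ValueError(
                f"unmatched biological replicates between {gene_name!r} and "
                f"{reference_gene!r} in {genotype}/{tissue}/{condition}"
            )
        dct[condition] = (tgt_ct - ref_ct).sort_index()
    ddct_mean = float(dct[treated].mean() - dct[control].mean())
    # per-bio-rep ΔΔCt spread (treated reps against the control mean ΔCt)
    per_rep = dct[treated] - dct[control].mean()
    sd = float(per_rep.std(ddof=1)) if len(per_rep) > 1 else 0.0
    ratio = 2.0 ** (-ddct_mean)
    direction = "up" if ratio >= 1 else "down"
    reported = ratio if direction == "up" else 1.0 / ratio
    return FoldChange(
        gene_name, genotype, tissue, ratio, direction, reported, sd, len(per_rep)
    )


def fold_change_table(
    records: pd.DataFrame,
    reference_gene: str = "actin",
    control: str = "control",
    treated: str = "salt",
) -> pd.DataFrame:
    """ΔΔCt fold changes for every (gene, genotype, tissue) cell in a Ct table."""
    rows = []
    targets = sorted(set(records["gene_name"]) - {reference_gene})
    for gene in targets:
        sub = records[records["gene_name"] == gene]
        for (genotype, tissue), _ in sub.groupby(["genotype", "tissue"]):
            fc = delta_delta_ct(
                records, gene, genotype, tissue, reference_gene, control, treated
            )
            rows.append(
                {
                    "gene_name": gene,
                    "genotype": genotype,
                    "tissue": tissue,
                    "ratio": fc.ratio,
                    "direction": fc.direction,
                    "reported_fold": fc.reported_fold,
                    "sd_ddct": fc.sd_ddct,
                    "n_bio": fc.n_bio,
                }
            )
    return pd.DataFrame(rows)


def _gap_runs(seq: str) -> list[tuple[int, int]]:
    """(start, length) of every maximal '-' run."""
    runs = []
    i = 0
    while i < len(seq):
        if seq[i] == "-":
            j = i
            while j < len(seq) and seq[j] == "-":
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def classify_mutations(seq_a: str, seq_b: str) -> MutationSummary:
    """Column-wise mutation classification of an aligned nucleotide pair.

    Deletions are gap runs in ``seq_b`` (bases present in A but lost from B);
    gap runs in ``seq_a`` are counted as insertion events.  Columns containing
    N are excluded from substitution counts; IUPAC ambiguity codes other than
    N are rejected.
    """
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    allowed = NUCLEOTIDES | {"N", "-"}
    for name, s in (("seq_a", a), ("seq_b", b)):
        bad = set(s) - allowed
        if bad:
            raise ValueError(f"{name} contains unsupported characters: {sorted(bad)}")
    transitions = transversions = identities = excluded = 0
    subs: list[tuple[int, str, str]] = []
    for i, (x, y) in enumerate(zip(a, b)):
        if x == "-" and y == "-":
            raise ValueError(f"column {i} is gapped in both sequences")
        if x == "-" or y == "-":
            continue  # handled by run counting
        if x == "N" or y == "N":
            excluded += 1
            continue
        if x == y:
            identities += 1
        else:
            if {x, y} <= PURINES or {x, y} <= PYRIMIDINES:
                transitions += 1
            else:
                transversions += 1
            subs.append((i, x, y))
    del_runs = _gap_runs(b)
    ins_runs = _gap_runs(a)
    return MutationSummary(
        deletion_events=len(del_runs),
        deleted_bases=sum(n for _, n in del_runs),
        insertion_events=len(ins_runs),
        inserted_bases=sum(n for _, n in ins_runs),
        transitions=transitions,
        transversions=transversions,
        identities=identities,
        excluded=excluded,
        substitutions=tuple(subs),
    )


def translate_cds(sequence: str, frame: int = 0) -> str:
    """Translate a CDS with the standard genetic code; stop codons become '*'.

    The trailing partial codon is dropped.  ``frame`` shifts the start by
    0–2 bases.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    seq = sequence.upper()
    if set(seq) - (NUCLEOTIDES | {"N"}):
        raise ValueError("sequence must be over A/C/G/T/N")
    coding = seq[frame:]
    coding = coding[: len(coding) - len(coding) % 3]
    if not coding:
        raise ValueError("no translatable codons in the requested frame")
    return str(Seq(coding).translate())


def find_motifs(
    aa_sequence: str, motifs: Iterable[str] = ("SGGG", "GR")
) -> list[MotifHit]:
    """Exact (possibly overlapping) motif occurrences in a protein sequence.

    Defaults scan for the HKT1 'selectivity filter' (Ser-Gly-Gly-Gly) and the
    membrane-anchoring Gly-Arg motif.
    """
    seq = aa_sequence.upper()
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise ValueError(f"unexpected amino-acid codes: {sorted(bad)}")
    hits = []
    for motif in motifs:
        positions = tuple(
            i for i in range(len(seq) - len(motif) + 1) if seq.startswith(motif, i)
        )
        hits.append(MotifHit(motif, positions, bool(positions)))
    return hits
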