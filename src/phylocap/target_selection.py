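"""Filter predicates for choosing capture targets from transcriptome contigs.

Candidate loci come annotated with pairwise identity between a closely
related species pair, ortholog copy number in a reference legume proteome,
intron structure, per-species read shares and BLAST evidence.  Two criteria
sets are implemented as pure, deterministic row filters:

* *phylogenetically useful*: variable enough between close relatives,
  single-copy, modest intron content, and expressed in all three source
  species without strong skew;
* *differentially expressed*: annotated with an enzyme (EC number) whose
  reads come predominantly from one species, backed by orthology evidence
  (reciprocal-best-hit membership or a strong match to the reference
  proteome) and one-to-three introns.

All inequality boundaries are strict exactly as worded in their definitions
(identity < 98.5, intron span < 1000 bp, shares within [25, 45], e-value
< 1e-40, share > 75%).  Every rejected row is tallied under the first
failing predicate so reject reasons sum to input minus kept.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "rpkm",
    "select_phylogenetic",
    "differential_ec_numbers",
    "select_differential",
]

CANDIDATE_COLUMNS = [
    "contig_id",
    "pairwise_identity_pct",
    "glycine_ortholog_count",
    "intron_count",
    "intron_total_bp",
    "read_share_pct_sp1",
    "read_share_pct_sp2",
    "read_share_pct_sp3",
    "in_rbh_set",
    "glycine_evalue",
    "ec_numbers",
]


def rpkm(mapped_reads: float, contig_length_bp: float, library_total_reads: float) -> float:
    """Reads per kilobase of contig per million mapped reads."""
    if contig_length_bp <= 0:
        raise ValueError("contig length must be positive")
    if library_total_reads <= 0:
        raise ValueError("library total reads must be positive")
    return mapped_reads / (contig_length_bp / 1_000.0) / (library_total_reads / 1_000_000.0)


_SHARE_COLS = ["read_share_pct_sp1", "read_share_pct_sp2", "read_share_pct_sp3"]


def _reject_tally(df: pd.DataFrame, predicates: list[tuple[str, pd.Series]]) -> pd.DataFrame:
    """Keep rows passing all predicates; tally rejects by first failure."""
    remaining = pd.Series(True, index=df.index)
    reasons: dict[str, int] = {}
    for name, ok in predicates:
        failed = remaining & ~ok.fillna(False)
        reasons[name] = int(failed.sum())
        remaining &= ok.fillna(False)
    kept = df.loc[remaining].copy()
    kept.attrs["reject_reasons"] = reasons
    kept.attrs["n_input"] = int(len(df))
    return kept


def select_phylogenetic(
    table: pd.DataFrame,
    max_identity: float = 98.5,
    intron_range: tuple[int, int] = (1, 3),
    max_intron_bp: int = 1000,
    share_bounds: tuple[float, float] = (25.0, 45.0),
) -> pd.DataFrame:
    """Rows satisfying the phylogenetic-utility criteria.

    identity strictly below 98.5% between the close species pair; exactly one
    ortholog copy; one to three introns spanning strictly less than 1 kb; and
    every species' read share within [25, 45] percent inclusive.  Rows with
    missing fields fail the corresponding predicate.
    """
    lo, hi = intron_range
    slo, shi = share_bounds
    shares_ok = pd.Series(True, index=table.index)
    for col in _SHARE_COLS:
        shares_ok &= (table[col] >= slo) & (table[col] <= shi)
    predicates = [
        ("identity", table["pairwise_identity_pct"] < max_identity),
        ("ortholog_count", table["glycine_ortholog_count"] == 1),
        ("intron_count", (table["intron_count"] >= lo) & (table["intron_count"] <= hi)),
        ("intron_span", table["intron_total_bp"] < max_intron_bp),
        ("read_share", shares_ok),
    ]
    return _reject_tally(table, predicates)


def differential_ec_numbers(
    expression: pd.DataFrame, share_cutoff: float = 75.0
) -> list[str]:
    """EC numbers whose summed reads come predominantly from one species.

    ``expression`` has one row per (ec_number, species) with a ``reads``
    column.  An EC qualifies when its maximum single-species share strictly
    exceeds ``share_cutoff`` percent; zero-total ECs are skipped with a
    warning.
    """
    required = {"ec_number", "species", "reads"}
    if not required.issubset(expression.columns):
        raise ValueError(f"expression table must have columns {sorted(required)}")
    totals = expression.groupby("ec_number")["reads"].sum()
    if (totals <= 0).all():
        raise ValueError("no EC number has positive total reads")
    zero = totals[totals <= 0]
    if len(zero):
        import warnings

        warnings.warn(f"skipping {len(zero)} EC number(s) with zero reads", stacklevel=2)
    by_species = expression.groupby(["ec_number", "species"])["reads"].sum()
    max_share = 100.0 * by_species.groupby("ec_number").max() / totals
    listed = max_share[(totals > 0) & (max_share > share_cutoff)]
    return sorted(listed.index)


def select_differential(
    table: pd.DataFrame,
    de_ecs: list[str],
    max_evalue: float = 1e-40,
    intron_range: tuple[int, int] = (1, 3),
) -> pd.DataFrame:
    """Rows annotated with a differentially expressed EC and orthology support.

    A row is kept when any of its EC numbers is in ``de_ecs``, it is either a
    reciprocal best hit or has a reference-proteome e-value strictly below
    ``max_evalue``, and its intron count lies in ``intron_range``.
    """
    de = set(de_ecs)

    def has_de_ec(ecs) -> bool:
        if isinstance(ecs, str):
            ecs = [e.strip() for e in ecs.split(",") if e.strip()]
        elif ecs is None or (np.isscalar(ecs) and pd.isna(ecs)):
            ecs = []
        return bool(de.intersection(ecs))

    lo, hi = intron_range
    predicates = [
        ("ec_listed", table["ec_numbers"].map(has_de_ec)),
        (
            "orthology",
            table["in_rbh_set"].astype(bool) | (table["glycine_evalue"] < max_evalue),
        ),
        ("intron_count", (table["intron_count"] >= lo) & (table["intron_count"] <= hi)),
    ]
    return _reject_tally(table, predicates)
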