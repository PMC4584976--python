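"""Paralog screening and alignment preparation for capture data.

Hybrid-capture datasets of recently radiated groups are prone to paralog
contamination: reads from different members of a gene family map onto a
single target, so an accession's consensus can represent one paralog in some
samples and a different paralog in others, corrupting downstream phylogenetic
signal.  This module implements the screening computations used to detect
and remove such loci from per-accession consensus data:

* mapping-stringency scan metrics (percent variant sites, standardised
  variant quality) for choosing an alignment-score threshold;
* base-call quality filtering (drop quality < 36 and indel calls) and
  IUPAC-ambiguity masking of consensus sequences;
* a coverage screen — a locus is discarded when too many accessions show
  depth far above their own across-locus average, the signature of a
  conserved domain attracting reads from several family members;
* an outgroup delta-variation screen — with a deeply divergent outgroup,
  removing it from an orthologous alignment removes a large share of the
  variable sites, whereas in a paralog-mixed alignment most variation stems
  from the ancient duplication and survives the outgroup's removal;
* column trimming by data presence, per-locus variable / parsimony-
  informative site statistics, and supermatrix concatenation with a
  partition table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LocusAlignment",
    "alignment_score_threshold",
    "percent_variant_sites",
    "standardized_quality",
    "filter_calls",
    "mask_ambiguities",
    "coverage_screen",
    "variability_stats",
    "outgroup_delta",
    "trim_missing_columns",
    "concatenate",
    "threshold_scan",
    "screen_loci",
]

IUPAC = set("ACGTNRYSWKMBDHV-")
_BASES = ("A", "C", "G", "T")
_MISSING = {"N", "-"}


# ---------------------------------------------------------------------------
# alignment container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusAlignment:
    """Equal-length sequences over {A,C,G,T,N,-} keyed by accession.

    Sequences are uppercased on construction; an optional outgroup accession
    may be designated for the delta-variation screen.
    """

    locus_id: str
    sequences: dict[str, str]
    outgroup: str | None = None

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("alignment needs at least one sequence")
        upper = {k: v.upper() for k, v in self.sequences.items()}
        object.__setattr__(self, "sequences", upper)
        lengths = {len(s) for s in upper.values()}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths in locus {self.locus_id}: {lengths}")
        bad = set("".join(upper.values())) - set("ACGTN-")
        if bad:
            raise ValueError(
                f"locus {self.locus_id} contains non-{{A,C,G,T,N,-}} symbols {sorted(bad)}; "
                "mask ambiguities first"
            )
        if self.outgroup is not None and self.outgroup not in upper:
            raise ValueError(f"outgroup {self.outgroup!r} absent from locus {self.locus_id}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def accessions(self) -> list[str]:
        return list(self.sequences)

    def matrix(self, exclude: set[str] | None = None) -> np.ndarray:
        """Character matrix (n_seqs, length) of single-byte strings."""
        keys = [a for a in self.sequences if not exclude or a not in exclude]
        return np.array([list(self.sequences[a]) for a in keys], dtype="U1")

    def drop(self, accessions: set[str]) -> "LocusAlignment":
        kept = {a: s for a, s in self.sequences.items() if a not in accessions}
        og = self.outgroup if self.outgroup not in accessions else None
        return LocusAlignment(self.locus_id, kept, og)

    def n_with_data(self) -> int:
        """Accessions with at least one non-missing base."""
        return sum(
            any(ch not in _MISSING for ch in seq) for seq in self.sequences.values()
        )


# ---------------------------------------------------------------------------
# mapping-threshold scan metrics
# ---------------------------------------------------------------------------

def alignment_score_threshold(constant: float, read_length: int) -> float:
    """Minimum mapper alignment score for a read of the given length.

    The score floor grows logarithmically with read length:
    ``constant + 8 * ln(read_length)``.  Raising the constant makes mapping
    more stringent, shedding paralogous reads first.
    """
    if read_length < 1:
        raise ValueError(f"read length must be >= 1, got {read_length}")
    return float(constant) + 8.0 * float(np.log(read_length))


def percent_variant_sites(calls: pd.DataFrame) -> float:
    """Percentage of base calls flagged as differing from the reference."""
    if len(calls) == 0:
        raise ValueError("empty call table")
    return 100.0 * float(calls["is_variant"].sum()) / float(len(calls))


def standardized_quality(calls: pd.DataFrame) -> float:
    """Mean quality of variant calls divided by mean quality of non-variant calls.

    The non-variant mean tracks the overall drift in call quality as mapping
    stringency changes, so the ratio isolates the quality of the variant
    calls themselves.  Returns NaN (with a warning) when either class is
    empty.
    """
    variant = calls.loc[calls["is_variant"], "quality"]
    non_variant = calls.loc[~calls["is_variant"], "quality"]
    if len(variant) == 0 or len(non_variant) == 0:
        warnings.warn(
            "standardized quality undefined: needs both variant and non-variant calls",
            stacklevel=2,
        )
        return float("nan")
    return float(variant.mean() / non_variant.mean())


def filter_calls(calls: pd.DataFrame, min_quality: float = 36.0) -> pd.DataFrame:
    """Drop calls below the quality floor and all indel calls.

    The boundary is strict on the low side: quality exactly equal to
    ``min_quality`` is retained.  Retention counts are stored in the result's
    ``attrs["retention"]`` and logged.
    """
    if min_quality < 0:
        raise ValueError("min_quality must be >= 0")
    keep = (calls["quality"] >= min_quality) & (~calls["is_indel"])
    out = calls.loc[keep].copy()
    retention = {
        "input": int(len(calls)),
        "kept": int(keep.sum()),
        "dropped_quality": int((calls["quality"] < min_quality).sum()),
        "dropped_indel": int((calls["is_indel"] & (calls["quality"] >= min_quality)).sum()),
    }
    out.attrs["retention"] = retention
    if retention["kept"] == 0:
        warnings.warn("no calls remain after filtering", stacklevel=2)
    logger.info("filter_calls: %s", retention)
    return out


def threshold_scan(runs: dict[float, pd.DataFrame]) -> pd.DataFrame:
    """Metric changes across consecutive mapping-stringency constants.

    ``runs`` maps an alignment-score constant to the call table produced at
    that stringency.  Returns one row per constant with the two scan metrics
    and their change from the previous (sorted) constant; inspecting where
    the percent-variant change accelerates and the standardised quality
    plateaus guides the choice of a conservative constant.
    """
    if len(runs) < 2:
        raise ValueError("threshold_scan needs call tables for at least two constants")
    consts = sorted(runs)
    rows = []
    for const in consts:
        calls = runs[const]
        rows.append(
            {
                "constant": const,
                "pct_variant": percent_variant_sites(calls),
                "std_quality": standardized_quality(calls),
            }
        )
    df = pd.DataFrame(rows)
    df["d_pct_variant"] = df["pct_variant"].diff()
    df["d_std_quality"] = df["std_quality"].diff()
    return df


# ---------------------------------------------------------------------------
# consensus masking
# ---------------------------------------------------------------------------

def mask_ambiguities(seq: str) -> str:
    """Uppercase a consensus sequence and convert IUPAC ambiguity codes to N.

    Heterozygous and paralog-induced ambiguous calls alike become missing
    data; A/C/G/T, N and gaps pass through.  Non-IUPAC symbols are an error.
    """
    up = seq.upper()
    bad = set(up) - IUPAC
    if bad:
        raise ValueError(f"non-IUPAC symbols in sequence: {sorted(bad)}")
    return "".join(ch if ch in "ACGTN-" else "N" for ch in up)


# ---------------------------------------------------------------------------
# locus screens
# ---------------------------------------------------------------------------

def coverage_screen(
    cov: pd.DataFrame,
    factor: float = 3.0,
    accession_fraction: float = 1.0 / 3.0,
) -> tuple[set[str], pd.DataFrame]:
    """Exclude loci whose depth is inflated across many accessions.

    For each accession the mean depth across its loci (cells with data) is
    the baseline; a locus is excluded when, among accessions with data at
    that locus, the fraction whose depth exceeds ``factor`` times their own
    baseline is strictly greater than ``accession_fraction``.  Such pileups
    indicate reads from several gene-family members collapsing onto a
    conserved region.

    Returns the excluded locus set and a per-locus report (fraction elevated,
    number of accessions with data, flag).
    """
    if cov.size == 0:
        raise ValueError("empty coverage matrix")
    depths = cov.to_numpy(dtype=float)
    acc_mean = np.nanmean(depths, axis=1)
    single = np.sum(~np.isnan(depths), axis=1) == 1
    if single.any():
        logger.warning(
            "coverage baseline degenerate (single locus) for accessions: %s",
            list(cov.index[single]),
        )
    with np.errstate(invalid="ignore"):
        elevated = depths > factor * acc_mean[:, None]
    has_data = ~np.isnan(depths)
    n_data = has_data.sum(axis=0)
    n_elev = (elevated & has_data).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_data > 0, n_elev / np.maximum(n_data, 1), 0.0)
    flag = frac > accession_fraction
    report = pd.DataFrame(
        {
            "locus_id": cov.columns,
            "n_accessions_with_data": n_data,
            "n_elevated": n_elev,
            "elevated_fraction": frac,
            "coverage_excluded": flag,
        }
    ).set_index("locus_id")
    return set(cov.columns[flag]), report


def _column_state_counts(mat: np.ndarray) -> np.ndarray:
    """Counts of A,C,G,T per column: shape (4, length)."""
    return np.array([(mat == b).sum(axis=0) for b in _BASES])


def variability_stats(
    aln: LocusAlignment,
    exclude: set[str] | None = None,
    denominator: str = "assessable",
) -> tuple[float, float]:
    """Proportions of variable and parsimony-informative columns.

    A column is variable when at least two distinct bases occur among the
    non-missing states, and parsimony-informative when at least two distinct
    bases each occur in at least two sequences.  N and '-' are missing.  The
    denominator counts columns with at least two non-missing states
    (``"assessable"``, default) or all columns (``"all"``).
    """
    mat = aln.matrix(exclude=exclude)
    if mat.shape[0] < 2:
        raise ValueError("variability_stats needs >= 2 sequences after exclusion")
    counts = _column_state_counts(mat)
    n_states = (counts > 0).sum(axis=0)
    n_present = counts.sum(axis=0)
    variable = n_states >= 2
    informative = (counts >= 2).sum(axis=0) >= 2
    if denominator == "assessable":
        denom = int((n_present >= 2).sum())
    elif denominator == "all":
        denom = mat.shape[1]
    else:
        raise ValueError("denominator must be 'assessable' or 'all'")
    if denom == 0:
        warnings.warn("alignment has no columns with >= 2 non-missing states", stacklevel=2)
        return (0.0, 0.0)
    return (float(variable.sum()) / denom, float(informative.sum()) / denom)


def outgroup_delta(
    aln: LocusAlignment,
    outgroup_id: str | None = None,
    cutoff: float = 8.0,
    mode: str = "relative",
) -> tuple[float, bool]:
    """Change in variable-site proportion when the outgroup is removed.

    For an orthologous locus the deeply divergent outgroup contributes a
    large share of the variation, so its removal drops the variable-site
    proportion substantially.  When paralogs are mixed across accessions the
    ancient duplication dominates the variation and survives the outgroup's
    removal, leaving the delta small: the locus is flagged for exclusion when
    the delta is at most ``cutoff`` percent.

    ``mode="relative"`` (default) measures 100 * (V_with - V_without) /
    V_with; ``mode="absolute"`` measures percentage points,
    100 * (V_with - V_without).  A locus with no variation at all
    (V_with = 0) is excluded outright.
    """
    og = outgroup_id or aln.outgroup
    if og is None or og not in aln.sequences:
        raise ValueError(f"outgroup {og!r} not present in locus {aln.locus_id}")
    if not any(ch not in _MISSING for ch in aln.sequences[og]):
        raise ValueError(f"outgroup {og!r} has no data in locus {aln.locus_id}")
    v_with, _ = variability_stats(aln)
    v_without, _ = variability_stats(aln, exclude={og})
    if v_with == 0.0:
        return (0.0, True)
    if mode == "relative":
        delta = 100.0 * (v_with - v_without) / v_with
    elif mode == "absolute":
        delta = 100.0 * (v_with - v_without)
    else:
        raise ValueError("mode must be 'relative' or 'absolute'")
    return (delta, delta <= cutoff)


# ---------------------------------------------------------------------------
# trimming and concatenation
# ---------------------------------------------------------------------------

def trim_missing_columns(aln: LocusAlignment, min_present_fraction: float = 0.5) -> LocusAlignment:
    """Remove columns where the fraction of non-missing states falls below the floor.

    The boundary is inclusive: a column with exactly the floor fraction
    present (e.g. half the sequences) is kept; only columns with data missing
    for *more* than the complement are removed.  Column order is preserved.
    """
    mat = aln.matrix()
    present = ~np.isin(mat, ("N", "-"))
    keep = present.mean(axis=0) >= min_present_fraction
    seqs = {
        acc: "".join(row) for acc, row in zip(aln.sequences, mat[:, keep])
    }
    return LocusAlignment(aln.locus_id, seqs, aln.outgroup)


def concatenate(
    alignments,
    accessions: list[str] | None = None,
    placeholder_length: int = 260,
    supermatrix_id: str = "supermatrix",
) -> tuple[LocusAlignment, pd.DataFrame]:
    """Concatenate per-locus alignments into a supermatrix plus partition table.

    Loci are laid out in the given order.  An accession absent from a locus
    receives Ns of that locus's aligned length; an entry of ``(locus_id,
    None)`` stands for a locus with no alignment at all and contributes
    ``placeholder_length`` Ns for every accession.  The partition table holds
    1-based inclusive start/end per locus and tiles the full length exactly.
    """
    entries = []
    for item in alignments:
        if isinstance(item, LocusAlignment):
            entries.append((item.locus_id, item))
        else:
            locus_id, aln = item
            entries.append((locus_id, aln))
    if not entries:
        raise ValueError("nothing to concatenate")
    if accessions is None:
        seen: dict[str, None] = {}
        for _, aln in entries:
            if aln is not None:
                for acc in aln.sequences:
                    seen[acc] = None
        accessions = list(seen)
    parts = []
    chunks: dict[str, list[str]] = {acc: [] for acc in accessions}
    pos = 1
    for locus_id, aln in entries:
        if aln is None:
            length = placeholder_length
            for acc in accessions:
                chunks[acc].append("N" * length)
        else:
            if len(set(aln.sequences)) != len(aln.sequences):
                raise ValueError(f"duplicate accession ids in locus {locus_id}")
            length = aln.length
            for acc in accessions:
                chunks[acc].append(aln.sequences.get(acc, "N" * length))
        parts.append({"locus_id": locus_id, "start": pos, "end": pos + length - 1})
        pos += length
    seqs = {acc: "".join(chunks[acc]) for acc in accessions}
    return LocusAlignment(supermatrix_id, seqs), pd.DataFrame(parts)


# ---------------------------------------------------------------------------
# combined screen
# ---------------------------------------------------------------------------

def screen_loci(
    alignments,
    coverage: pd.DataFrame | None = None,
    outgroup: str | None = None,
    cutoff: float = 8.0,
    cov_factor: float = 3.0,
    cov_fraction: float = 1.0 / 3.0,
    delta_mode: str = "relative",
) -> pd.DataFrame:
    """Run the coverage and outgroup screens plus per-locus statistics.

    Returns a deterministic per-locus report: screen flags, outgroup delta,
    variable / parsimony-informative proportions (ingroup, i.e. outgroup
    excluded when designated) and accession counts.  A locus passes when no
    applied screen flags it.
    """
    cov_excluded: set[str] = set()
    cov_report = None
    if coverage is not None:
        cov_excluded, cov_report = coverage_screen(coverage, cov_factor, cov_fraction)
    rows = []
    for aln in alignments:
        og = outgroup or aln.outgroup
        delta, og_flag = (np.nan, False)
        if og is not None and og in aln.sequences:
            delta, og_flag = outgroup_delta(aln, og, cutoff=cutoff, mode=delta_mode)
        exclude = {og} if og in aln.sequences else set()
        ingroup = aln.drop(exclude) if exclude else aln
        if ingroup.n_with_data() >= 2:
            prop_var, prop_pi = variability_stats(ingroup)
        else:
            prop_var, prop_pi = (np.nan, np.nan)
        cov_flag = aln.locus_id in cov_excluded
        rows.append(
            {
                "locus_id": aln.locus_id,
                "coverage_excluded": cov_flag,
                "outgroup_delta": delta,
                "outgroup_excluded": og_flag,
                "prop_variable": prop_var,
                "prop_parsimony_informative": prop_pi,
                "n_accessions_with_data": aln.n_with_data(),
                "passed": not (cov_flag or og_flag),
            }
        )
    report = pd.DataFrame(rows).set_index("locus_id")
    if cov_report is not None:
        report = report.join(cov_report[["elevated_fraction"]], how="left")
    return report
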