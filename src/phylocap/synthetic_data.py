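"""Synthetic datasets with known truth for every pipeline input.

Everything the pipeline consumes can be generated here under controlled
conditions: triplet mutation configurations drawn from the structured
coalescent divergence model, three-sequence alignments that invert exactly
to those configurations, capture datasets with a planted fraction of
paralog-contaminated loci (inconsistently sampled gene-family copies, the
outgroup nested inside one copy's clade, inflated coverage over a conserved
window), mapping-stringency call tables, and candidate-locus annotation
tables with planted filter outcomes.  Each generator records its seed and
parameters in a truth sidecar so screens and estimators can be scored
against known labels.

Defaults emulate a targeted-enrichment study of a recent radiation: ~500 bp
unlinked nuclear loci at per-locus theta of 1-2, shallow ingroup divergence,
a deeply diverged outgroup, and gene-family splits predating the outgroup.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .locus_screening import LocusAlignment
from .triplet_model import DivergenceParams, TripletConfiguration

__all__ = [
    "SimulatedGenealogy",
    "SyntheticTruth",
    "DepthModel",
    "QualityModel",
    "CaptureDataset",
    "planted_alignment",
    "simulate_genealogy",
    "simulate_triplet_configs",
    "configs_to_alignments",
    "simulate_capture_dataset",
    "simulate_candidate_table",
]

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# truth sidecar
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Generating parameters and per-locus labels for a synthetic dataset."""

    kind: str
    seed: int
    params: dict
    per_locus: pd.DataFrame | None = None

    def to_json(self, path) -> None:
        payload = {
            "kind": self.kind,
            "seed": self.seed,
            "params": self.params,
            "per_locus": None
            if self.per_locus is None
            else self.per_locus.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        per_locus = (
            pd.DataFrame(payload["per_locus"]) if payload["per_locus"] is not None else None
        )
        return cls(payload["kind"], payload["seed"], payload["params"], per_locus)


# ---------------------------------------------------------------------------
# coalescent triplet loci
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedGenealogy:
    """A realised triplet genealogy: first coalescing pair and both times."""

    first_pair: str  # 'ab', 'ac' or 'bc'
    u: float         # first coalescence time (2Ne generations)
    w: float         # final coalescence time

    def __post_init__(self) -> None:
        if self.first_pair not in ("ab", "ac", "bc"):
            raise ValueError(f"bad pair {self.first_pair!r}")
        if not 0 <= self.u <= self.w:
            raise ValueError("times must satisfy 0 <= u <= w")

    def branch_lengths(self) -> tuple[float, float, float]:
        """Unrooted branch lengths (l_a, l_b, l_c)."""
        long = 2.0 * self.w - self.u
        if self.first_pair == "bc":
            return (long, self.u, self.u)
        if self.first_pair == "ac":
            return (self.u, long, self.u)
        return (self.u, self.u, long)


def simulate_genealogy(params: DivergenceParams, rng: np.random.Generator) -> SimulatedGenealogy:
    """Draw one genealogy from the structured three-population coalescent.

    Lineages b and c may coalesce (rate 1) on [t1, t1+t2]; all lineages
    surviving to t1+t2 enter the ancestral population, where the first of
    the three pairs coalesces at rate 3 (pair uniform) and the last two at
    rate 1.  Pairs containing lineage a therefore never coalesce before
    t1 + t2.
    """
    t1, t2 = params.t1, params.t2
    x = rng.exponential()
    if x < t2:
        u = t1 + x
        w = t1 + t2 + rng.exponential()
        return SimulatedGenealogy("bc", u, w)
    u = t1 + t2 + rng.exponential() / 3.0
    pair = ("ab", "ac", "bc")[rng.integers(3)]
    return SimulatedGenealogy(pair, u, u + rng.exponential())


def _simulate_branch_lengths(
    params: DivergenceParams, n_loci: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised genealogy draws; returns (n_loci, 3) branch lengths."""
    t1, t2 = params.t1, params.t2
    A = t1 + t2
    x = rng.exponential(size=n_loci)
    bc_early = x < t2
    y = rng.exponential(size=n_loci) / 3.0
    v = rng.exponential(size=n_loci)
    u = np.where(bc_early, t1 + x, A + y)
    w = np.where(bc_early, A + v, u + v)
    pair = np.where(bc_early, 2, rng.integers(0, 3, size=n_loci))  # 0=ab,1=ac,2=bc
    long = 2.0 * w - u
    lens = np.stack([u, u, u], axis=1)
    lens[pair == 2, 0] = long[pair == 2]
    lens[pair == 1, 1] = long[pair == 1]
    lens[pair == 0, 2] = long[pair == 0]
    return lens


def simulate_triplet_configs(
    params: DivergenceParams, n_loci: int, seed: int
) -> tuple[list[TripletConfiguration], SyntheticTruth]:
    """Draw unlinked loci: a genealogy per locus, Poisson mutations per branch.

    Mutation counts on the three unrooted branches are independent Poisson
    with mean (theta/2) * length; under infinite sites these are exactly the
    minority-state site counts (s_a, s_b, s_c).
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    lens = _simulate_branch_lengths(params, n_loci, rng)
    counts = rng.poisson(params.theta / 2.0 * lens)
    configs = [
        TripletConfiguration(f"locus_{i:06d}", int(r[0]), int(r[1]), int(r[2]))
        for i, r in enumerate(counts)
    ]
    per_locus = pd.DataFrame(
        {
            "locus_id": [c.locus_id for c in configs],
            "s_a": counts[:, 0],
            "s_b": counts[:, 1],
            "s_c": counts[:, 2],
        }
    )
    truth = SyntheticTruth(
        kind="triplet_configs",
        seed=seed,
        params={"theta": params.theta, "t1": params.t1, "t2": params.t2, "n_loci": n_loci},
        per_locus=per_locus,
    )
    return configs, truth


def configs_to_alignments(
    configs, locus_length: int, seed: int, names: tuple[str, str, str] = ("a", "b", "c")
) -> list[LocusAlignment]:
    """Materialise configurations as three-sequence alignments.

    Each mutation occupies a distinct column (infinite sites): the carrying
    sequence gets a different base from the shared background there, so
    reducing the alignment back to site patterns inverts the construction
    exactly.
    """
    rng = np.random.default_rng(seed)
    out = []
    for cfg in configs:
        total = cfg.s_a + cfg.s_b + cfg.s_c
        if locus_length < total:
            raise ValueError(
                f"locus_length {locus_length} < {total} mutations at {cfg.locus_id}"
            )
        background = rng.choice(_BASES, size=locus_length)
        mat = np.tile(background, (3, 1))
        cols = rng.choice(locus_length, size=total, replace=False)
        owner = np.repeat([0, 1, 2], [cfg.s_a, cfg.s_b, cfg.s_c])
        for col, seq_idx in zip(cols, owner):
            current = mat[seq_idx, col]
            alternatives = _BASES[_BASES != current]
            mat[seq_idx, col] = rng.choice(alternatives)
        seqs = {name: "".join(row) for name, row in zip(names, mat)}
        out.append(LocusAlignment(cfg.locus_id, seqs))
    return out


def planted_alignment(
    locus_id: str,
    n_seqs: int,
    length: int,
    n_variable: int,
    n_informative: int,
    seed: int,
    names: list[str] | None = None,
) -> tuple[LocusAlignment, dict]:
    """Alignment with exactly the requested variable/informative column counts.

    Informative columns carry two states on two sequences each; the remaining
    variable columns carry a singleton state.  No missing data, so variable
    and parsimony-informative proportions are exactly ``n_variable / length``
    and ``n_informative / length``.  Requires ``n_seqs >= 4`` when
    ``n_informative > 0``.
    """
    if n_informative > n_variable:
        raise ValueError("informative columns are a subset of variable columns")
    if n_variable > length:
        raise ValueError("more variable columns than columns")
    if n_informative > 0 and n_seqs < 4:
        raise ValueError("parsimony-informative columns need >= 4 sequences")
    rng = np.random.default_rng(seed)
    names = names or [f"seq{i:02d}" for i in range(n_seqs)]
    background = rng.choice(_BASES, size=length)
    mat = np.tile(background, (n_seqs, 1))
    cols = rng.choice(length, size=n_variable, replace=False)
    for i, col in enumerate(cols):
        current = mat[0, col]
        alt = rng.choice(_BASES[_BASES != current])
        carriers = rng.choice(n_seqs, size=2 if i < n_informative else 1, replace=False)
        mat[carriers, col] = alt
    truth = {
        "n_variable": n_variable,
        "n_informative": n_informative,
        "length": length,
        "prop_variable": n_variable / length,
        "prop_parsimony_informative": n_informative / length,
    }
    return LocusAlignment(locus_id, {n: "".join(r) for n, r in zip(names, mat)}), truth


# ---------------------------------------------------------------------------
# capture datasets with planted paralogs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DepthModel:
    """Negative-binomial read depth around an accession-specific mean.

    ``conserved_multiplier`` inflates depth at paralogous loci, emulating
    reads from several gene-family members piling onto a conserved window.
    """

    mean: float = 30.0
    accession_sd_log: float = 0.3
    dispersion: float = 10.0
    conserved_multiplier: float = 4.0


@dataclass(frozen=True)
class QualityModel:
    """Phred-quality and contamination behaviour across mapping stringencies.

    Spurious variant calls from paralog co-mapping (rate
    ``contamination_rate``, low quality) persist while the alignment-score
    constant is below ``critical_constant`` and vanish above it; genuine
    variants (rate ``base_variant_rate``) persist throughout.
    """

    non_variant_mean: float = 40.0
    variant_mean: float = 42.0
    spurious_mean: float = 25.0
    sd: float = 3.0
    base_variant_rate: float = 0.01
    contamination_rate: float = 0.03
    critical_constant: float = 300.0


@dataclass
class CaptureDataset:
    """Per-locus alignments, coverage matrix, scan call tables and truth."""

    alignments: list
    coverage: pd.DataFrame
    call_tables: dict
    truth: SyntheticTruth


def _mutate(seq: np.ndarray, distance: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor substitution over a branch of the given expected length
    (substitutions per site)."""
    p = 0.75 * (1.0 - np.exp(-4.0 * distance / 3.0))
    out = seq.copy()
    hits = rng.random(seq.size) < p
    idx = np.flatnonzero(hits)
    if idx.size:
        shift = rng.integers(1, 4, size=idx.size)
        codes = np.searchsorted(_BASES, out[idx])
        out[idx] = _BASES[(codes + shift) % 4]
    return out


def simulate_capture_dataset(
    n_accessions: int = 20,
    n_loci: int = 100,
    paralog_fraction: float = 0.25,
    paralog_divergence: float = 1.0,
    locus_length: int = 500,
    ingroup_divergence: float = 0.01,
    outgroup_divergence: float = 0.15,
    outgroup_name: str = "OUTGROUP",
    missing_fraction: float = 0.03,
    depth_model: DepthModel = DepthModel(),
    quality_model: QualityModel = QualityModel(),
    scan_constants: tuple = (20, 60, 100, 140, 180, 220, 260, 300, 340, 380, 420),
    scan_sites: int = 5000,
    seed: int = 0,
) -> CaptureDataset:
    """Generate a capture dataset with a planted fraction of paralogous loci.

    Orthologous loci evolve on a star-like ingroup with a deeply divergent
    outgroup.  Paralogous loci carry two gene-family copies that split at
    ``paralog_divergence`` (per copy branch, predating the outgroup); each
    ingroup accession's consensus is drawn from a random copy while the
    outgroup is nested within copy 1's clade, and read depth at these loci is
    inflated by the conserved-window multiplier.  Truth labels, the coverage
    matrix and one call table per mapping-stringency constant are returned
    alongside the alignments.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if not 0.0 <= paralog_fraction <= 1.0:
        raise ValueError("paralog_fraction must be in [0, 1]")
    if paralog_divergence <= ingroup_divergence:
        raise ValueError("paralog divergence must exceed ingroup divergence")
    rng = np.random.default_rng(seed)
    accessions = [f"ACC{i:03d}" for i in range(n_accessions)]
    n_paralog = int(round(paralog_fraction * n_loci))
    is_paralog = np.zeros(n_loci, dtype=bool)
    is_paralog[rng.choice(n_loci, size=n_paralog, replace=False)] = True

    acc_mean = depth_model.mean * np.exp(
        rng.normal(0.0, depth_model.accession_sd_log, size=n_accessions)
    )

    alignments, cov_rows, records = [], [], []
    for j in range(n_loci):
        locus_id = f"locus_{j:04d}"
        root = rng.choice(_BASES, size=locus_length)
        seqs: dict[str, str] = {}
        if is_paralog[j]:
            copy1 = _mutate(root, paralog_divergence, rng)
            copy2 = _mutate(root, paralog_divergence, rng)
            # outgroup nested inside copy 1's clade
            seqs[outgroup_name] = "".join(_mutate(copy1, outgroup_divergence, rng))
            copy_choice = rng.integers(0, 2, size=n_accessions)
            for i, acc in enumerate(accessions):
                source = copy1 if copy_choice[i] == 0 else copy2
                seqs[acc] = "".join(_mutate(source, ingroup_divergence, rng))
        else:
            seqs[outgroup_name] = "".join(_mutate(root, outgroup_divergence, rng))
            for acc in accessions:
                seqs[acc] = "".join(_mutate(root, ingroup_divergence, rng))
        # missing accession x locus cells: no data at all
        missing = rng.random(n_accessions) < missing_fraction
        depth_mean = acc_mean * (
            depth_model.conserved_multiplier if is_paralog[j] else 1.0
        )
        r = depth_model.dispersion
        depth = rng.negative_binomial(r, r / (r + depth_mean)).astype(float)
        for i, acc in enumerate(accessions):
            if missing[i]:
                seqs[acc] = "N" * locus_length
                depth[i] = np.nan
        alignments.append(LocusAlignment(locus_id, seqs, outgroup=outgroup_name))
        cov_rows.append(depth)
        records.append(
            {
                "locus_id": locus_id,
                "is_paralog": bool(is_paralog[j]),
                "n_missing_accessions": int(missing.sum()),
            }
        )

    coverage = pd.DataFrame(
        np.column_stack(cov_rows), index=accessions, columns=[r["locus_id"] for r in records]
    )
    call_tables = {
        float(c): _scan_call_table(c, quality_model, scan_sites, rng)
        for c in scan_constants
    }
    truth = SyntheticTruth(
        kind="capture",
        seed=seed,
        params={
            "n_accessions": n_accessions,
            "n_loci": n_loci,
            "paralog_fraction": paralog_fraction,
            "paralog_divergence": paralog_divergence,
            "locus_length": locus_length,
            "ingroup_divergence": ingroup_divergence,
            "outgroup_divergence": outgroup_divergence,
            "conserved_multiplier": depth_model.conserved_multiplier,
        },
        per_locus=pd.DataFrame(records),
    )
    return CaptureDataset(alignments, coverage, call_tables, truth)


def _scan_call_table(
    constant: float, qm: QualityModel, n_sites: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Call table at one mapping stringency for the threshold scan."""
    contaminated = constant < qm.critical_constant
    p_true = qm.base_variant_rate
    p_spur = qm.contamination_rate if contaminated else 0.0
    u = rng.random(n_sites)
    kind = np.where(u < p_true, 1, np.where(u < p_true + p_spur, 2, 0))
    quality = rng.normal(qm.non_variant_mean, qm.sd, size=n_sites)
    quality[kind == 1] = rng.normal(qm.variant_mean, qm.sd, size=int((kind == 1).sum()))
    quality[kind == 2] = rng.normal(qm.spurious_mean, qm.sd, size=int((kind == 2).sum()))
    calls = rng.choice(_BASES, size=n_sites)
    return pd.DataFrame(
        {
            "locus_id": "scan_locus",
            "position": np.arange(1, n_sites + 1),
            "call": calls,
            "quality": np.clip(quality, 0.0, None),
            "is_variant": kind > 0,
            "is_indel": False,
            "depth": rng.poisson(30, size=n_sites),
        }
    )


# ---------------------------------------------------------------------------
# candidate-locus tables
# ---------------------------------------------------------------------------

def simulate_candidate_table(
    n_rows: int,
    seed: int,
    planted_pass_counts: dict[str, int] | None = None,
    n_de_ecs: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Candidate-locus and expression tables with planted filter outcomes.

    ``planted_pass_counts`` gives the exact number of rows passing each
    criteria set (keys ``"phylo"`` and ``"differential"``); planted passers
    of one set are constructed to fail the other, and filler rows fail both.
    Returns (candidate table, expression table, truth); the expression table
    contains exactly ``n_de_ecs`` EC numbers whose reads are >75% from one
    species, which are the ECs carried by the differential passers.
    """
    planted = {"phylo": 5, "differential": 5, **(planted_pass_counts or {})}
    n_phylo, n_diff = planted["phylo"], planted["differential"]
    if n_phylo + n_diff > n_rows:
        raise ValueError("planted pass counts exceed n_rows")
    rng = np.random.default_rng(seed)

    de_ecs = [f"1.1.1.{i}" for i in range(1, n_de_ecs + 1)]
    other_ecs = [f"2.7.7.{i}" for i in range(1, 4)]
    species = ["sp1", "sp2", "sp3"]

    expr_rows = []
    for ec in de_ecs:
        dominant = rng.integers(3)
        reads = rng.integers(5, 40, size=3)
        reads[dominant] = int(reads.sum() * 4)  # > 75% share guaranteed
        expr_rows += [
            {"ec_number": ec, "species": sp, "reads": int(r)} for sp, r in zip(species, reads)
        ]
    for ec in other_ecs:
        reads = rng.integers(80, 120, size=3)  # near-even: max share < 75%
        expr_rows += [
            {"ec_number": ec, "species": sp, "reads": int(r)} for sp, r in zip(species, reads)
        ]
    expression = pd.DataFrame(expr_rows)

    def passing_shares() -> np.ndarray:
        s1 = rng.uniform(28.0, 40.0)
        s2 = rng.uniform(max(25.0, 55.0 - s1), min(45.0, 75.0 - s1))
        return np.array([s1, s2, 100.0 - s1 - s2])

    rows = []
    labels = (
        ["phylo"] * n_phylo + ["differential"] * n_diff + ["fail"] * (n_rows - n_phylo - n_diff)
    )
    for i, label in enumerate(labels):
        row = {
            "contig_id": f"contig_{i:04d}",
            "pairwise_identity_pct": rng.uniform(95.0, 98.4),
            "glycine_ortholog_count": 1,
            "intron_count": int(rng.integers(1, 4)),
            "intron_total_bp": int(rng.integers(100, 999)),
            "in_rbh_set": True,
            "glycine_evalue": 10.0 ** rng.uniform(-120, -90),
            "ec_numbers": "",
        }
        shares = passing_shares()
        if label == "phylo":
            row["ec_numbers"] = other_ecs[int(rng.integers(len(other_ecs)))]  # fails differential
        elif label == "differential":
            row["pairwise_identity_pct"] = rng.uniform(98.6, 99.9)  # fails phylo
            row["ec_numbers"] = de_ecs[int(rng.integers(len(de_ecs)))]
            if rng.random() < 0.5:
                row["in_rbh_set"] = False
                row["glycine_evalue"] = 10.0 ** rng.uniform(-80, -45)  # still < 1e-40
        else:
            breakers = rng.choice(4, size=int(rng.integers(1, 3)), replace=False)
            if 0 in breakers:
                row["pairwise_identity_pct"] = rng.uniform(98.5, 99.9)
            if 1 in breakers:
                row["glycine_ortholog_count"] = int(rng.integers(2, 5))
            if 2 in breakers:
                row["intron_count"] = int(rng.choice([0, 4, 6]))
            if 3 in breakers:
                shares = np.array([60.0, 22.0, 18.0])
            if 0 not in breakers and 1 not in breakers and 2 not in breakers and 3 not in breakers:
                row["intron_total_bp"] = int(rng.integers(1000, 3000))
            # never allow a filler row to pass differential
            row["ec_numbers"] = ""
            if row["intron_count"] in (1, 2, 3) and 2 not in breakers:
                row["intron_count"] = int(rng.choice([0, 5]))
        row["read_share_pct_sp1"], row["read_share_pct_sp2"], row["read_share_pct_sp3"] = shares
        row["planted_label"] = label
        rows.append(row)
    table = pd.DataFrame(rows)
    truth = SyntheticTruth(
        kind="candidates",
        seed=seed,
        params={"n_rows": n_rows, **planted, "de_ecs": de_ecs},
        per_locus=table[["contig_id", "planted_label"]].rename(
            columns={"contig_id": "locus_id"}
        ),
    )
    return table.drop(columns=["planted_label"]), expression, truth
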