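"""Consensus significance across enrichment methods and its permutation null.

Each gene set receives three p-values (rotation, competitive, preranked
GSEA).  They are combined by the harmonic mean p-value

    HMP = (sum_i w_i) / (sum_i w_i / p_i),

a combiner valid under dependence, then Benjamini-Hochberg adjusted across
all sets tested in the contrast; a set is called significant when the
FDR-adjusted HMP is below alpha.  The raw HMP is used directly (no
asymptotically exact recalibration) since the FDR step follows immediately;
the Landau-tail recalibration is available as an option.

The validation experiment reruns the whole enrichment + consensus stack on
datasets whose gene labels have been randomly permuted against the expression
rows — destroying gene-set membership while preserving every marginal
property of the expression data — and counts how often anything reaches
significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import DesignSpec, adjust_bh
from .enrichment import (
    RankedList,
    competitive_test,
    fit_linear_model,
    gsea_preranked,
    rotation_test,
)
from .gene_sets import GeneSetCollection

logger = logging.getLogger(__name__)

METHODS = ("rotation", "competitive", "gsea")


def harmonic_mean_p(p, w=None) -> float:
    """Weighted harmonic mean of p-values.

    All p must lie in (0, 1]; weights are positive and are normalised to
    sum to one (equal by default).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if (p <= 0).any():
        raise ValueError("p-values must be strictly positive")
    if (p > 1).any():
        raise ValueError("p-values must be <= 1")
    if w is None:
        w = np.full(p.size, 1.0 / p.size)
    else:
        w = np.asarray(w, dtype=float)
        if (w <= 0).any():
            raise ValueError("weights must be positive")
        w = w / w.sum()
    return float(w.sum() / np.sum(w / p))


def hmp_exact(p, w=None) -> float:
    """Asymptotically exact HMP tail probability (Landau distribution).

    Optional recalibration of :func:`harmonic_mean_p`; uses the standard
    Landau tail with location/scale set by the number of tests.
    """
    from scipy.stats import landau

    p = np.asarray(p, dtype=float)
    hmp = harmonic_mean_p(p, w)
    # 1/HMP is asymptotically Landau(log L + 0.874368, pi/2) under the null
    loc = np.log(p.size) + 0.874368
    return float(min(1.0, landau.sf(1.0 / hmp, loc=loc, scale=np.pi / 2.0)))


@dataclass
class ConsensusTable:
    """Per-set consensus results for one contrast."""

    table: pd.DataFrame            # indexed by set name
    contrast: str
    alpha: float = 0.05

    @property
    def significant(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def build_consensus(method_results: dict[str, pd.DataFrame], contrast: str,
                    weights=None, alpha: float = 0.05,
                    exact_hmp: bool = False) -> ConsensusTable:
    """Combine the three per-method tables into the consensus table.

    ``method_results`` maps method name -> DataFrame with columns
    ``set`` and ``p`` (rotation / competitive / gsea as produced by
    :mod:`hmpenrich.enrichment`).  Sets missing from any method are excluded
    with a log entry; a wholesale mismatch of universes is an error.
    """
    missing = [m for m in METHODS if m not in method_results]
    if missing:
        raise ValueError(f"missing method results: {missing}")
    per_method = {
        m: method_results[m].set_index("set") for m in METHODS
    }
    common = set(per_method[METHODS[0]].index)
    union = set()
    for m in METHODS:
        common &= set(per_method[m].index)
        union |= set(per_method[m].index)
    if not common:
        raise ValueError("no gene set reported by all three methods")
    dropped = union - common
    if dropped:
        if len(dropped) > max(3, 0.5 * len(union)):
            raise ValueError(
                f"method set universes are inconsistent ({len(dropped)} of "
                f"{len(union)} sets not shared)"
            )
        logger.info("excluding %d sets not reported by all methods: %s",
                    len(dropped), sorted(dropped)[:5])
    names = sorted(common)
    combiner = hmp_exact if exact_hmp else harmonic_mean_p
    rows = {}
    for name in names:
        ps = [float(per_method[m].loc[name, "p"]) for m in METHODS]
        rows[name] = combiner(ps, weights)
    table = pd.DataFrame({
        "p_rotation": [per_method["rotation"].loc[n, "p"] for n in names],
        "p_competitive": [per_method["competitive"].loc[n, "p"] for n in names],
        "p_gsea": [per_method["gsea"].loc[n, "p"] for n in names],
        "hmp": [rows[n] for n in names],
    }, index=pd.Index(names, name="set"))
    table["fdr_hmp"] = adjust_bh(table["hmp"].to_numpy())
    table["significant"] = table["fdr_hmp"] < alpha
    gsea_tab = per_method["gsea"]
    table["direction"] = [gsea_tab.loc[n].get("direction", "") for n in names]
    if "leading_edge" in gsea_tab.columns:
        table["leading_edge"] = [gsea_tab.loc[n, "leading_edge"] for n in names]
    return ConsensusTable(table=table, contrast=contrast, alpha=alpha)


# ---------------------------------------------------------------------------
# enrichment + consensus on one expression state (reused by the null runs)


@dataclass
class EnrichmentState:
    """Everything needed to (re)run enrichment + consensus for contrasts."""

    logcpm: pd.DataFrame
    design: DesignSpec
    ranked: dict[str, RankedList]            # contrast -> ranked list
    sets: GeneSetCollection
    n_perm: int = 2_000
    n_rot: int = 1_999
    gsea_weight: float = 1.0
    alpha: float = 0.05
    weights: list[float] | None = None
    rho_floor: float | None = None


def run_enrichment(state: EnrichmentState, contrast: str,
                   rng: np.random.Generator | int | None = 0,
                   fit=None, gsea_null_cache: dict | None = None):
    """Three methods + consensus for one contrast.

    Returns ``(ConsensusTable, dict of per-method tables)``.  ``fit`` and
    ``gsea_null_cache`` allow reuse of label-invariant computations across
    repeated calls on relabelled data (the permutation null).
    """
    rng = np.random.default_rng(rng)
    if fit is None:
        fit = fit_linear_model(state.logcpm, state.design)
    results = {
        "rotation": rotation_test(
            state.logcpm, state.design, contrast, state.sets,
            n_rot=state.n_rot, rng=rng,
        ),
        "competitive": competitive_test(
            state.logcpm, state.design, contrast, state.sets, fit=fit,
            rho_floor=state.rho_floor,
        ),
        "gsea": gsea_preranked(
            state.ranked[contrast], state.sets,
            n_perm=state.n_perm, gsea_weight=state.gsea_weight, rng=rng,
            null_cache=gsea_null_cache,
        ),
    }
    consensus = build_consensus(
        results, contrast, weights=state.weights, alpha=state.alpha
    )
    return consensus, results


# ---------------------------------------------------------------------------
# gene-label permutation null


@dataclass
class PermutationReport:
    n_permutations: int
    seed: int | None
    counts: pd.DataFrame           # permutation x (contrast, n_significant_*)

    def max_consensus_significant(self) -> int:
        return int(self.counts["n_significant_consensus"].max())

    def fraction_any_significant(self) -> float:
        per_perm = self.counts.groupby("permutation")[
            "n_significant_consensus"
        ].sum()
        return float((per_perm > 0).mean())


def _non_identity_permutation(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform draw over non-identity permutations of ``n`` items."""
    if n < 2:
        raise ValueError("cannot permute fewer than 2 labels")
    while True:
        perm = rng.permutation(n)
        if not np.all(perm == np.arange(n)):
            return perm


def permute_label_validation(state: EnrichmentState, n_perm: int = 100,
                             seed: int | None = 0,
                             contrasts: list[str] | None = None) -> PermutationReport:
    """Re-run enrichment + consensus on gene-label-permuted datasets.

    Each permutation reassigns gene identifiers to expression rows (and to
    the ranked statistics), which breaks gene-set membership while leaving
    the expression matrix and the DE statistic distribution untouched.  The
    identity shuffle is excluded by construction.  Per-method significance
    uses each method's own BH-adjusted p-values at ``state.alpha``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    contrasts = contrasts or list(state.ranked)
    genes = list(state.logcpm.index)
    n = len(genes)
    # label-invariant pieces, reused across permutations: the linear-model
    # fit (values do not change under relabelling) and the GSEA null ES
    # distributions (they depend only on the ranked values and set sizes)
    shared_fit = fit_linear_model(state.logcpm, state.design)
    gsea_caches: dict[str, dict] = {c: {} for c in contrasts}
    records = []
    for b in range(n_perm):
        perm = _non_identity_permutation(rng, n)
        relabel = pd.Index([genes[i] for i in perm])
        logcpm_b = state.logcpm.copy()
        logcpm_b.index = relabel
        # relabel ranked lists consistently with the expression rows
        lut = dict(zip(genes, relabel))
        ranked_b = {}
        for c in contrasts:
            old = state.ranked[c].stats
            ranked_b[c] = RankedList(
                stats=pd.Series(
                    old.to_numpy(), index=[lut[g] for g in old.index]
                ),
                contrast=c,
            )
        state_b = EnrichmentState(
            logcpm=logcpm_b,
            design=state.design,
            ranked=ranked_b,
            sets=state.sets,
            n_perm=state.n_perm,
            n_rot=state.n_rot,
            gsea_weight=state.gsea_weight,
            alpha=state.alpha,
            weights=state.weights,
            rho_floor=state.rho_floor,
        )
        for c in contrasts:
            consensus, per_method = run_enrichment(
                state_b, c, rng=rng, fit=shared_fit,
                gsea_null_cache=gsea_caches[c],
            )
            rec = {
                "permutation": b,
                "contrast": c,
                "n_significant_consensus": consensus.n_significant(),
            }
            for mname, tab in per_method.items():
                rec[f"n_significant_{mname}"] = int(
                    (adjust_bh(tab["p"].to_numpy()) < state.alpha).sum()
                )
            records.append(rec)
        logger.info("permutation %d/%d done", b + 1, n_perm)
    return PermutationReport(
        n_permutations=n_perm, seed=seed, counts=pd.DataFrame(records)
    )


# ---------------------------------------------------------------------------
# leading-edge overlaps


def leading_edge_overlap(gsea_results: pd.DataFrame, significant_sets=None,
                         min_shared: int = 3) -> pd.DataFrame:
    """Exclusive (upset-style) intersections among GSEA leading edges.

    Every gene is assigned to the exact combination of leading edges that
    contain it; combinations of two or more sets with at least ``min_shared``
    genes are reported, largest first.
    """
    tab = gsea_results.set_index("set")
    names = list(significant_sets) if significant_sets is not None else list(tab.index)
    edges = {}
    for name in names:
        le = tab.loc[name, "leading_edge"] if name in tab.index else ""
        members = [g for g in str(le).split(",") if g] if pd.notna(le) else []
        edges[name] = set(members)
    gene_combo: dict[str, tuple[str, ...]] = {}
    for gene in set().union(*edges.values()) if edges else set():
        combo = tuple(sorted(n for n in names if gene in edges[n]))
        gene_combo.setdefault(gene, combo)
    counts: dict[tuple[str, ...], list[str]] = {}
    for gene, combo in gene_combo.items():
        if len(combo) >= 2:
            counts.setdefault(combo, []).append(gene)
    rows = [
        {
            "sets": ",".join(combo),
            "n_sets": len(combo),
            "n_shared": len(genes),
            "genes": ",".join(sorted(genes)),
        }
        for combo, genes in counts.items()
        if len(genes) >= min_shared
    ]
    out = pd.DataFrame(rows, columns=["sets", "n_sets", "n_shared", "genes"])
    if len(out):
        out = out.sort_values(
            ["n_shared", "sets"], ascending=[False, True]
        ).reset_index(drop=True)
    return out
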