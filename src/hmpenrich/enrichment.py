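"""Three independent gene-set tests per contrast.

* a **self-contained rotation test** (roast/fry family): the observed set
  statistic is the mean moderated t of the members; its null is generated by
  random rotations of the residual space of the fitted linear model, which
  preserve the nuisance structure and inter-gene correlation exactly;
* a **competitive test** (camera family): moderated t statistics converted to
  normal-equivalent z scores, compared between set and non-set genes with the
  variance inflated by ``VIF = 1 + (m - 1) * rho_bar`` where ``rho_bar`` is
  the mean inter-gene residual correlation of the set;
* **preranked GSEA**: the weighted Kolmogorov-Smirnov-like running sum over a
  ranked list, with p-values from random same-size gene sets and leading-edge
  extraction at the enrichment-score extremum.

All three operate on the same logCPM matrix / design (GSEA through the ranked
DE statistics) and report per-set p-values that are later combined by the
harmonic mean p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import polygamma

from .de import DEResult, DesignSpec
from .gene_sets import GeneSetCollection

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# moderated t machinery (shared by the rotation and competitive tests)


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def squeeze_var(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Empirical-Bayes scaled-inverse-chi-square prior for gene variances.

    Returns ``(d0, s0_sq)`` fitted by moments on log variances; ``d0`` may be
    ``inf`` when the variances are consistent with a common value.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-300)
    z = np.log(s2)
    e = z - polygamma(0, df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = np.exp(emean + polygamma(0, d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(emean)
    return float(d0), float(s0_sq)


def posterior_var(s2: np.ndarray, df: float, d0: float, s0_sq: float) -> np.ndarray:
    if np.isinf(d0):
        return np.full_like(np.asarray(s2, dtype=float), s0_sq)
    return (d0 * s0_sq + df * s2) / (d0 + df)


@dataclass
class LinearFit:
    """OLS fit of logCPM on the design, with EB-moderated variances."""

    coefs: pd.DataFrame            # genes x coefficients
    residuals: np.ndarray          # genes x samples
    s2: np.ndarray                 # genes, residual variances
    df_residual: float
    d0: float
    s0_sq: float
    xtx_inv: np.ndarray
    design: DesignSpec

    def moderated_t(self, coef: str) -> pd.Series:
        j = list(self.coefs.columns).index(coef)
        s2_post = posterior_var(self.s2, self.df_residual, self.d0, self.s0_sq)
        se = np.sqrt(self.xtx_inv[j, j] * s2_post)
        t = self.coefs.iloc[:, j].to_numpy() / se
        return pd.Series(t, index=self.coefs.index, name=f"t_{coef}")

    @property
    def df_total(self) -> float:
        return self.df_residual + (0.0 if np.isinf(self.d0) else self.d0)


def fit_linear_model(logcpm: pd.DataFrame, design: DesignSpec) -> LinearFit:
    """Per-gene least-squares fit with empirical-Bayes variance shrinkage."""
    Y = logcpm.to_numpy(dtype=float)
    X = design.matrix.loc[logcpm.columns].to_numpy(dtype=float)
    n, p = X.shape
    df = n - p
    if df < 1:
        raise ValueError("no residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    pinv = xtx_inv @ X.T
    coefs = Y @ pinv.T
    resid = Y - coefs @ X.T
    s2 = (resid**2).sum(axis=1) / df
    d0, s0_sq = squeeze_var(s2, df)
    return LinearFit(
        coefs=pd.DataFrame(coefs, index=logcpm.index, columns=design.matrix.columns),
        residuals=resid,
        s2=s2,
        df_residual=float(df),
        d0=d0,
        s0_sq=s0_sq,
        xtx_inv=xtx_inv,
        design=design,
    )


def t_to_z(t: np.ndarray, df: float) -> np.ndarray:
    """Map t statistics to standard-normal equivalents, preserving sign."""
    t = np.asarray(t, dtype=float)
    tail = stats.t.sf(np.abs(t), df)
    tail = np.clip(tail, 1e-300, None)
    return np.sign(t) * stats.norm.isf(tail)


# ---------------------------------------------------------------------------
# ranking


@dataclass
class RankedList:
    """Genes sorted by a signed ranking statistic, decreasing.

    Ties are broken by gene ID, so the order is a deterministic total order.
    """

    stats: pd.Series
    contrast: str = ""
    metric: str = "signed_neglog10p"

    def __post_init__(self) -> None:
        if self.stats.isna().any():
            raise ValueError("ranking statistics contain NaN")
        frame = self.stats.rename("stat").rename_axis("gene").reset_index()
        frame = frame.sort_values(
            ["stat", "gene"], ascending=[False, True], kind="stable"
        )
        self.stats = frame.set_index("gene")["stat"]

    @property
    def genes(self) -> list[str]:
        return list(self.stats.index)

    def __len__(self) -> int:
        return len(self.stats)


def rank_genes(de: DEResult, contrast: str, cap: float = 300.0) -> RankedList:
    """Signed significance ranking: ``sign(logFC) * -log10(p)``.

    Zero p-values are capped at magnitude ``cap`` (with a log entry) so the
    statistic stays finite.
    """
    tab = de.contrast(contrast)
    with np.errstate(divide="ignore"):
        mag = -np.log10(tab["p"].to_numpy())
    n_capped = int(np.sum(~np.isfinite(mag) | (mag > cap)))
    if n_capped:
        logger.info("capping %d ranking statistics at %g", n_capped, cap)
    mag = np.minimum(mag, cap)
    stat = np.sign(tab["logFC"].to_numpy()) * mag
    return RankedList(
        stats=pd.Series(stat, index=tab.index), contrast=contrast
    )


# ---------------------------------------------------------------------------
# preranked GSEA


def _running_es(positions: np.ndarray, weights: np.ndarray, n_genes: int,
                total_weight: float):
    """Signed extremum of the running sum for one set.

    ``positions`` are sorted 0-based hit ranks; ``weights`` the corresponding
    hit increments (already |stat|**gsea_weight).  Returns
    ``(es, extremum_hit_index)`` where the index is the hit at (positive ES)
    or just after (negative ES) the extremum.
    """
    m = positions.size
    miss_step = 1.0 / (n_genes - m)
    cum_hit = np.cumsum(weights) / total_weight
    hits_before = np.arange(m)
    # deviation just after each hit, and just before each hit
    after = cum_hit - (positions - hits_before) * miss_step
    before = np.concatenate(([0.0], cum_hit[:-1])) - (positions - hits_before) * miss_step
    i_max = int(np.argmax(after))
    i_min = int(np.argmin(before))
    es_pos = after[i_max]
    es_neg = before[i_min]
    if es_pos >= -es_neg:
        return float(es_pos), i_max, True
    return float(es_neg), i_min, False


def _null_es(positions: np.ndarray, stat_w: np.ndarray, n_genes: int) -> np.ndarray:
    """Vectorised signed-extremum ES for many same-size random sets.

    ``positions``: (n_perm, m) sorted hit ranks; ``stat_w``: per-rank hit
    weights for the whole list.
    """
    n_perm, m = positions.shape
    miss_step = 1.0 / (n_genes - m)
    w = stat_w[positions]
    tot = w.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    cum_hit = np.cumsum(w, axis=1) / tot
    drift = (positions - np.arange(m)[None, :]) * miss_step
    after = cum_hit - drift
    before = np.concatenate(
        [np.zeros((n_perm, 1)), cum_hit[:, :-1]], axis=1
    ) - drift
    es_pos = after.max(axis=1)
    es_neg = before.min(axis=1)
    return np.where(es_pos >= -es_neg, es_pos, es_neg)


def _ordered_samples(rng: np.random.Generator, n_draws: int, n_genes: int,
                     k: int, chunk: int = 500) -> np.ndarray:
    """(n_draws, k) ordered samples without replacement from range(n_genes).

    Each row's length-m prefix is a uniform random m-subset in exchangeable
    order (selection by k smallest of iid uniforms, ordered by those
    uniforms).
    """
    out = np.empty((n_draws, k), dtype=np.int64)
    done = 0
    while done < n_draws:
        b = min(chunk, n_draws - done)
        u = rng.random((b, n_genes))
        part = np.argpartition(u, k - 1, axis=1)[:, :k]
        order = np.argsort(np.take_along_axis(u, part, axis=1), axis=1)
        out[done:done + b] = np.take_along_axis(part, order, axis=1)
        done += b
    return out


def gsea_preranked(ranked: RankedList, sets: GeneSetCollection,
                   n_perm: int = 10_000, gsea_weight: float = 1.0,
                   rng: np.random.Generator | int | None = 0,
                   null_cache: dict | None = None) -> pd.DataFrame:
    """Preranked GSEA with a random-gene-set null.

    The null shares one batch of random rank samples across all sets: each
    draw is an ordered random sample of the largest set size, whose length-m
    prefix is a uniform random m-subset — so every set size reuses the same
    draws, as in the fast GSEA implementation.  Draws come in antithetic
    mirrored pairs (a sample and its rank-reversed image), which makes the
    null exactly symmetric under negation of the ranking statistic;
    ``n_perm`` is rounded up to an even count.  p-values are one-tailed on
    the matching ES sign with the +1 small-sample correction; NES divides ES
    by the mean |ES| of same-sign null draws.

    The null ES distribution depends only on the ranked statistic values and
    the set size, so callers testing many membership assignments against the
    same ranked values (e.g. the gene-label permutation null) may pass a
    ``null_cache`` dict, reused across calls, mapping set size to the null
    ES sample.
    """
    rng = np.random.default_rng(rng)
    genes = ranked.genes
    n_genes = len(genes)
    pos = {g: i for i, g in enumerate(genes)}
    stat_abs = np.abs(ranked.stats.to_numpy())
    stat_w = stat_abs**gsea_weight

    member_pos: dict[str, np.ndarray] = {}
    for name, members in sets.sets.items():
        p = np.array(sorted(pos[g] for g in members if g in pos), dtype=int)
        if p.size == 0:
            logger.info("set %s disjoint from ranked universe; skipped", name)
            continue
        if p.size >= n_genes:
            logger.info("set %s covers the whole universe; skipped", name)
            continue
        member_pos[name] = p

    sizes_needed = {p.size for p in member_pos.values()}
    if null_cache is None or any(m not in null_cache for m in sizes_needed):
        max_m = max((p.size for p in member_pos.values()), default=1)
        half = (n_perm + 1) // 2
        draws = _ordered_samples(rng, half, n_genes, max_m)
        samples = np.concatenate([draws, n_genes - 1 - draws], axis=0)
    else:
        samples = None

    rows = []
    for name, p_hit in member_pos.items():
        m = p_hit.size
        w_hit = stat_w[p_hit]
        tot = w_hit.sum()
        if tot == 0:
            tot = 1.0
        es, ext_i, positive = _running_es(p_hit.astype(float), w_hit, n_genes, tot)
        if null_cache is not None and m in null_cache:
            null = null_cache[m]
        else:
            null = _null_es(np.sort(samples[:, :m], axis=1), stat_w, n_genes)
            if null_cache is not None:
                null_cache[m] = null
        if es >= 0:
            same = null[null >= 0]
            b_count = int(np.sum(same >= es))
        else:
            same = null[null <= 0]
            b_count = int(np.sum(same <= es))
        pval = (b_count + 1.0) / (same.size + 1.0)
        denom = np.abs(same).mean() if same.size else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        if positive:
            lead = p_hit[: ext_i + 1]
        else:
            lead = p_hit[ext_i:]
        leading = [genes[i] for i in lead]
        rows.append({
            "set": name,
            "method": "gsea",
            "p": pval,
            "direction": "up" if es >= 0 else "down",
            "es": es,
            "nes": nes,
            "stat": es,
            "size": m,
            "n_more_extreme": b_count,
            "n_resamples": int(same.size),
            "leading_edge": ",".join(leading),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# competitive (camera-style) test


def competitive_test(logcpm: pd.DataFrame, design: DesignSpec, contrast: str,
                     sets: GeneSetCollection,
                     fit: LinearFit | None = None,
                     rho_floor: float | None = None) -> pd.DataFrame:
    """Inter-gene-correlation-adjusted competitive gene-set test.

    Set and non-set moderated z scores are compared by a two-sample test
    whose set-side variance is inflated by ``VIF = 1 + (m - 1) * rho_bar``,
    the variance of a mean of correlated genes.  Because the VIF is itself
    estimated from the ``n - p`` residual dimensions, the statistic is
    referred to a t distribution with ``n - p`` degrees of freedom.

    ``rho_floor`` imposes a lower bound on the estimated correlation (a
    fixed prior correlation of 0.01 is a common conservative default in the
    field); ``None`` uses the per-set estimate as is, including negative
    values — clipping at zero would make the test conservative.
    """
    if fit is None:
        fit = fit_linear_model(logcpm, design)
    coef = f"genotype_{contrast}" if f"genotype_{contrast}" in fit.coefs.columns \
        else contrast
    t = fit.moderated_t(coef)
    z = pd.Series(t_to_z(t.to_numpy(), fit.df_total), index=t.index)
    n_genes = len(z)
    sd = float(z.to_numpy().std(ddof=1))
    # unit-normalised residual rows: pairwise inner products are the
    # inter-gene correlations, and ||sum of unit rows||^2 / m = VIF directly
    resid = fit.residuals
    norms = np.linalg.norm(resid, axis=1, keepdims=True)
    unit = resid / np.maximum(norms, 1e-300)
    gene_pos = {g: i for i, g in enumerate(logcpm.index)}

    rows = []
    for name, members in sets.sets.items():
        idx = [gene_pos[g] for g in members if g in gene_pos]
        m = len(idx)
        if m == 0 or m >= n_genes:
            logger.info("set %s not testable (size %d); skipped", name, m)
            continue
        if m < 2:
            rho = 0.0
            vif = 1.0
        else:
            vif = float((unit[idx].sum(axis=0) ** 2).sum()) / m
            rho = (vif - 1.0) / (m - 1)
            if rho_floor is not None and rho < rho_floor:
                rho = rho_floor
                vif = 1.0 + (m - 1) * rho
        vif = max(vif, 1e-3)
        z_set = float(z.to_numpy()[idx].mean())
        mask = np.ones(n_genes, dtype=bool)
        mask[idx] = False
        z_rest = float(z.to_numpy()[mask].mean())
        se = sd * np.sqrt(vif / m + 1.0 / (n_genes - m))
        stat = (z_set - z_rest) / se
        pval = float(2.0 * stats.t.sf(abs(stat), fit.df_residual))
        pval = min(max(pval, np.nextafter(0, 1)), 1.0)
        rows.append({
            "set": name,
            "method": "competitive",
            "p": pval,
            "direction": "up" if stat >= 0 else "down",
            "stat": stat,
            "rho_bar": rho,
            "vif": vif,
            "size": m,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rotation (self-contained) test


def _effects_decomposition(logcpm: pd.DataFrame, design: DesignSpec,
                           contrast: str):
    """Rotate the data into (tested-effect, residual) coordinates.

    The design is reordered so the tested coefficient comes last; the QR
    effects transform then isolates one coordinate carrying that coefficient
    (orthogonalised against nuisance) plus ``n - p`` residual coordinates.
    Returns ``(z (G, d), d)`` with the effect coordinate first.
    """
    X = design.matrix.loc[logcpm.columns].copy()
    coef = f"genotype_{contrast}" if f"genotype_{contrast}" in X.columns else contrast
    if coef not in X.columns:
        raise ValueError(f"contrast {contrast!r} not in design")
    others = [c for c in X.columns if c != coef]
    Xr = X[others + [coef]].to_numpy(dtype=float)
    n, p = Xr.shape
    q, r = np.linalg.qr(Xr, mode="complete")
    if r[p - 1, p - 1] < 0:  # keep the effect coordinate sign-aligned with beta
        q[:, p - 1] = -q[:, p - 1]
    Y = logcpm.to_numpy(dtype=float)
    effects = Y @ q
    z = effects[:, p - 1:]
    return z, z.shape[1]


def rotation_test(logcpm: pd.DataFrame, design: DesignSpec, contrast: str,
                  sets: GeneSetCollection, n_rot: int = 9_999,
                  rng: np.random.Generator | int | None = 0,
                  chunk: int = 512) -> pd.DataFrame:
    """Self-contained rotation test (Monte-Carlo roast/fry style).

    Per set, the observed statistic is the mean moderated t of the members;
    the null replaces the effect coordinate of every gene by its projection
    on a random direction of the (effect + residual) sphere, which leaves
    nuisance effects and inter-gene correlation intact.  The two-sided
    directional p is ``(b + 1) / (n_rot + 1)``.
    """
    if n_rot < 99:
        logger.warning("n_rot=%d gives very coarse p-value granularity", n_rot)
    rng = np.random.default_rng(rng)
    z, d = _effects_decomposition(logcpm, design, contrast)
    if d < 2:
        raise ValueError("need at least one residual degree of freedom")
    # genes carrying no variation beyond the nuisance fit are exactly null;
    # zero their coordinates so fp noise is not divided by a tiny variance
    y_scale = (logcpm.to_numpy(dtype=float) ** 2).sum(axis=1)
    degenerate = (z**2).sum(axis=1) <= 1e-14 * (y_scale + 1.0)
    z[degenerate] = 0.0
    df = d - 1
    s2 = (z[:, 1:] ** 2).sum(axis=1) / df
    d0, s0_sq = squeeze_var(s2, df)
    s2_post = np.maximum(posterior_var(s2, df, d0, s0_sq), 1e-300)
    t_obs = z[:, 0] / np.sqrt(s2_post)

    gene_pos = {g: i for i, g in enumerate(logcpm.index)}
    set_idx = {}
    for name, members in sets.sets.items():
        idx = np.array([gene_pos[g] for g in members if g in gene_pos], dtype=int)
        if idx.size == 0:
            logger.info("set %s disjoint from expression matrix; skipped", name)
            continue
        set_idx[name] = idx

    obs = {name: float(t_obs[idx].mean()) for name, idx in set_idx.items()}
    exceed = {name: 0 for name in set_idx}
    total = (z**2).sum(axis=1)
    done = 0
    while done < n_rot:
        b = min(chunk, n_rot - done)
        r = rng.standard_normal((b, d))
        r /= np.linalg.norm(r, axis=1, keepdims=True)
        z0 = z @ r.T                                  # (G, b)
        s2_rot = np.maximum(total[:, None] - z0**2, 0.0) / df
        t_rot = z0 / np.sqrt(posterior_var(s2_rot, df, d0, s0_sq))
        for name, idx in set_idx.items():
            stat_rot = t_rot[idx].mean(axis=0)
            exceed[name] += int(np.sum(np.abs(stat_rot) >= abs(obs[name])))
        done += b

    rows = []
    for name, idx in set_idx.items():
        pval = (exceed[name] + 1.0) / (n_rot + 1.0)
        rows.append({
            "set": name,
            "method": "rotation",
            "p": pval,
            "direction": "up" if obs[name] >= 0 else "down",
            "stat": obs[name],
            "size": int(idx.size),
            "n_more_extreme": exceed[name],
            "n_resamples": n_rot,
        })
    return pd.DataFrame(rows)
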