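"""Per-gene negative-binomial GLMs for differential expression.

Each gene's counts are modelled as NB(mu_ij, phi_i) with
``log mu_ij = x_j' beta_i + log(effective library size_j)``.  The design uses
the wild-type genotype as intercept, genotype coefficients for each mutant
group, sex (female reference), tank (tank 1 reference) and any latent
unwanted-variation columns W.  Dispersions are estimated by maximising the
Cox-Reid adjusted profile likelihood (APL) on a log-spaced grid and shrunk
toward an abundance-dependent trend by weighted-likelihood empirical Bayes.
Coefficients are tested by likelihood-ratio chi-square tests (per-coefficient
and jointly over all genotype coefficients), with Benjamini-Hochberg FDR
adjustment per contrast.

Counts may be fractional (pseudo-aligner output); the NB log-likelihood is
evaluated in its gamma-function form, which is continuous in the response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .counts import CountMatrix, cpm

logger = logging.getLogger(__name__)

_IRLS_TOL = 1e-8
_IRLS_MAXIT = 50
_ETA_CLIP = 45.0  # keeps exp(eta) finite for any realistic library size


# ---------------------------------------------------------------------------
# design


@dataclass
class DesignSpec:
    """Design matrix with named genotype coefficients.

    ``matrix`` is samples x coefficients; ``genotype_coefs`` lists the
    columns whose contrasts against the wild-type intercept are reported.
    """

    matrix: pd.DataFrame
    genotype_coefs: list[str] = field(default_factory=list)

    @classmethod
    def from_metadata(cls, metadata: pd.DataFrame,
                      W: pd.DataFrame | None = None,
                      genotype_ref: str = "wildtype",
                      sex_ref: str = "female",
                      tank_ref: str | None = None) -> "DesignSpec":
        cols: dict[str, np.ndarray] = {"intercept": np.ones(len(metadata))}
        geno_levels = [g for g in _ordered_levels(metadata["genotype"])
                       if g != genotype_ref]
        if genotype_ref not in set(metadata["genotype"]):
            raise ValueError(f"reference genotype {genotype_ref!r} absent")
        for level in geno_levels:
            cols[f"genotype_{level}"] = (metadata["genotype"] == level).astype(float).to_numpy()
        if "sex" in metadata and metadata["sex"].nunique() > 1:
            for level in _ordered_levels(metadata["sex"]):
                if level != sex_ref:
                    cols[f"sex_{level}"] = (metadata["sex"] == level).astype(float).to_numpy()
        if "tank" in metadata and metadata["tank"].nunique() > 1:
            levels = _ordered_levels(metadata["tank"])
            ref = tank_ref if tank_ref is not None else levels[0]
            for level in levels:
                if level != ref:
                    cols[f"tank_{level}"] = (metadata["tank"] == level).astype(float).to_numpy()
        if W is not None:
            for name in W.columns:
                cols[str(name)] = W.loc[metadata.index, name].to_numpy(dtype=float)
        mat = pd.DataFrame(cols, index=metadata.index)
        if np.linalg.matrix_rank(mat.to_numpy()) < mat.shape[1]:
            raise ValueError("design matrix is not of full column rank")
        return cls(
            matrix=mat,
            genotype_coefs=[f"genotype_{level}" for level in geno_levels],
        )

    @property
    def n_coefs(self) -> int:
        return self.matrix.shape[1]

    def contrast_names(self) -> list[str]:
        return [c.removeprefix("genotype_") for c in self.genotype_coefs]


def _ordered_levels(series: pd.Series) -> list[str]:
    """First-appearance order, so metadata row order sets reference levels."""
    return list(dict.fromkeys(series))


# ---------------------------------------------------------------------------
# NB GLM internals (vectorised across genes)


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Continuous-response NB log-likelihood, summed over samples.

    ``y``: (G, n) counts (fractional allowed); ``mu``: (G, n) means;
    ``phi``: (G, 1) or scalar dispersions.  Returns (G,).
    """
    phi = np.maximum(phi, 1e-12)
    r = 1.0 / phi
    mu = np.maximum(mu, 1e-12)
    ll = (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
        + y * np.log(phi * mu / (1.0 + phi * mu))
        - r * np.log1p(phi * mu)
    )
    return ll.sum(axis=1)


def _irls(y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi: np.ndarray,
          beta0: np.ndarray | None = None):
    """Batched IRLS for NB GLMs sharing one design.

    ``y`` (G, n), ``X`` (n, p), ``offset`` (n,), ``phi`` (G, 1) or scalar.
    Returns ``(beta (G, p), mu (G, n), loglik (G,), converged (G,))``.
    """
    g_count, n = y.shape
    p = X.shape[1]
    phi = np.broadcast_to(np.asarray(phi, dtype=float).reshape(-1, 1), (g_count, 1))
    if beta0 is None:
        beta = np.zeros((g_count, p))
        # intercept start: log mean rate; assumes column 0 is the intercept
        rate = (y / np.exp(offset)[None, :]).mean(axis=1)
        beta[:, 0] = np.log(np.maximum(rate, 1e-10))
    else:
        beta = beta0.copy()
    eye = np.eye(p) * 1e-10
    last_ll = np.full(g_count, -np.inf)
    converged = np.zeros(g_count, dtype=bool)
    for _ in range(_IRLS_MAXIT):
        eta = np.clip(beta @ X.T + offset[None, :], -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        ll = nb_loglik(y, mu, phi)
        active = ~converged
        newly = active & (np.abs(ll - last_ll) < _IRLS_TOL * (np.abs(ll) + 1.0))
        converged |= newly
        last_ll = ll
        if converged.all():
            break
        w = mu / (1.0 + phi * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu
        xtwx = np.einsum("ji,gj,jk->gik", X, w, X) + eye[None, :, :]
        xtwz = np.einsum("ji,gj,gj->gi", X, w, z)
        try:
            new_beta = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            new_beta = np.einsum(
                "gik,gk->gi", np.linalg.pinv(xtwx), xtwz
            )
        upd = ~converged
        # step-halving where the full Fisher step decreases the likelihood
        step = np.ones((g_count, 1))
        for _half in range(6):
            cand = beta + step * (new_beta - beta)
            eta_c = np.clip(cand @ X.T + offset[None, :], -_ETA_CLIP, _ETA_CLIP)
            ll_c = nb_loglik(y, np.exp(eta_c), phi)
            bad = upd & (ll_c < ll - 1e-12)
            if not bad.any():
                break
            step[bad] *= 0.5
        cand = beta + step * (new_beta - beta)
        beta[upd] = cand[upd]
    eta = np.clip(beta @ X.T + offset[None, :], -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    return beta, mu, nb_loglik(y, mu, phi), converged


def adjusted_profile_loglik(y: np.ndarray, X: np.ndarray, offset: np.ndarray,
                            phi: float | np.ndarray) -> np.ndarray:
    """Cox-Reid APL at dispersion ``phi``: profile log-likelihood minus
    half the log-determinant of the Fisher information of beta."""
    _, mu, ll, _ = _irls(y, X, offset, phi)
    phi_col = np.broadcast_to(
        np.asarray(phi, dtype=float).reshape(-1, 1), (y.shape[0], 1)
    )
    w = mu / (1.0 + phi_col * mu)
    info = np.einsum("ji,gj,jk->gik", X, w, X) + np.eye(X.shape[1])[None] * 1e-10
    _, logdet = np.linalg.slogdet(info)
    return ll - 0.5 * logdet


# ---------------------------------------------------------------------------
# dispersion estimation


@dataclass
class DispersionResult:
    dispersion: pd.Series          # shrunk per-gene phi
    trended: pd.Series
    genewise: pd.Series            # unshrunk grid maximiser
    flagged: pd.Series             # True where phi fell back to the trend
    prior_df: float


_GRID = np.exp(np.linspace(np.log(1e-4), np.log(10.0), 19))


def _interp_argmax(grid_log: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Row-wise argmax with quadratic interpolation in log-dispersion."""
    idx = np.argmax(values, axis=1)
    out = grid_log[idx]
    interior = (idx > 0) & (idx < len(grid_log) - 1)
    i = idx[interior]
    rows = np.flatnonzero(interior)
    y0 = values[rows, i - 1]
    y1 = values[rows, i]
    y2 = values[rows, i + 1]
    denom = y0 - 2.0 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    step = grid_log[1] - grid_log[0]
    out[interior] = grid_log[i] + shift * step
    return out


def estimate_dispersions(m: CountMatrix, design: DesignSpec,
                         prior_df: float = 10.0,
                         grid: np.ndarray = _GRID,
                         trend_span: float = 0.1) -> DispersionResult:
    """Grid APL maximisation with a moving-average abundance trend and
    weighted-likelihood empirical-Bayes shrinkage.

    For each grid dispersion the APL of every gene is computed (one batched
    IRLS per grid point); the trend is a moving average of APL rows over
    genes ordered by average logCPM (window ``trend_span`` of genes); each
    gene then maximises ``APL_g + (prior_df / residual_df) * APL_trend_g``
    with quadratic interpolation between grid points.
    """
    y = m.counts.to_numpy(dtype=float)
    X = design.matrix.to_numpy(dtype=float)
    offset = np.log(m.effective_lib_sizes.to_numpy(dtype=float))
    g_count, n = y.shape
    df_res = n - X.shape[1]
    if df_res <= 0:
        raise ValueError("need more samples than coefficients")

    apl = np.empty((g_count, len(grid)))
    for k, phi in enumerate(grid):
        apl[:, k] = adjusted_profile_loglik(y, X, offset, float(phi))

    # abundance trend: moving average of APL curves over abundance order
    abundance = np.log2(cpm(m).to_numpy() + 0.5).mean(axis=1)
    order = np.argsort(abundance, kind="stable")
    window = max(11, int(trend_span * g_count) | 1)
    window = min(window, g_count if g_count % 2 == 1 else g_count - 1)
    sorted_apl = apl[order]
    kernel = np.ones(window) / window
    padded = np.pad(sorted_apl, ((window // 2, window // 2), (0, 0)), mode="edge")
    trend_sorted = np.empty_like(sorted_apl)
    for k in range(len(grid)):
        trend_sorted[:, k] = np.convolve(padded[:, k], kernel, mode="valid")
    apl_trend = np.empty_like(apl)
    apl_trend[order] = trend_sorted

    grid_log = np.log(grid)
    trended = np.exp(_interp_argmax(grid_log, apl_trend))
    genewise = np.exp(_interp_argmax(grid_log, apl))
    weighted = apl + (prior_df / df_res) * apl_trend
    shrunk = np.exp(_interp_argmax(grid_log, weighted))

    # all-zero (or otherwise uninformative) genes fall back to the trend
    flat = np.ptp(apl, axis=1) < 1e-8
    shrunk[flat] = trended[flat]
    genes = m.counts.index
    return DispersionResult(
        dispersion=pd.Series(shrunk, index=genes, name="dispersion"),
        trended=pd.Series(trended, index=genes, name="trended"),
        genewise=pd.Series(genewise, index=genes, name="genewise"),
        flagged=pd.Series(flat, index=genes, name="flagged"),
        prior_df=prior_df,
    )


def common_dispersion_apl(y_gene: np.ndarray, X: np.ndarray, offset: np.ndarray,
                          phi: float) -> float:
    """Single-gene APL at one dispersion (grid-search building block)."""
    return float(
        adjusted_profile_loglik(y_gene[None, :], X, offset, float(phi))[0]
    )


# ---------------------------------------------------------------------------
# fitting and testing


@dataclass
class DEResult:
    """Tidy per-gene, per-contrast test results plus the joint genotype test.

    ``table`` columns: gene, contrast, logFC (log2), logCPM, dispersion,
    p, fdr, de, converged.  ``joint`` columns: p, fdr (ANOVA-type test over
    all genotype coefficients, indexed by gene).
    """

    table: pd.DataFrame
    joint: pd.DataFrame
    design: DesignSpec
    alpha: float = 0.05

    def contrast(self, name: str) -> pd.DataFrame:
        sub = self.table[self.table["contrast"] == name]
        return sub.set_index("gene")

    def n_de(self, name: str) -> int:
        return int(self.contrast(name)["de"].sum())


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values cannot be adjusted")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def fit_and_test(m: CountMatrix, design: DesignSpec,
                 dispersions: DispersionResult | pd.Series,
                 alpha: float = 0.05,
                 contrasts: list[str] | None = None,
                 joint: bool = True) -> DEResult:
    """Fit the full NB GLM and run likelihood-ratio tests.

    Per genotype coefficient, the reduced model drops that column; the joint
    (ANOVA-type) test drops all genotype columns at once.  Genes whose full
    fit fails to converge are reported with p = 1 (conservative).

    ``contrasts`` restricts the per-coefficient tests to a subset of the
    genotype contrasts (``[]`` skips them); ``joint=False`` skips the joint
    test.  Both default to testing everything.
    """
    phi = (dispersions.dispersion if isinstance(dispersions, DispersionResult)
           else dispersions)
    phi_arr = phi.loc[m.counts.index].to_numpy(dtype=float)
    y = m.counts.to_numpy(dtype=float)
    X = design.matrix.to_numpy(dtype=float)
    offset = np.log(m.effective_lib_sizes.to_numpy(dtype=float))
    genes = m.counts.index
    coef_names = list(design.matrix.columns)

    tested_coefs = (design.genotype_coefs if contrasts is None
                    else [f"genotype_{c}" for c in contrasts])
    unknown = [c for c in tested_coefs if c not in coef_names]
    if unknown:
        raise ValueError(f"unknown contrasts: {unknown}")

    beta, _, ll_full, conv = _irls(y, X, offset, phi_arr)
    logcpm_avg = np.log2(cpm(m).to_numpy() + 0.5).mean(axis=1)

    rows = []
    for coef in tested_coefs:
        j = coef_names.index(coef)
        keep = [k for k in range(X.shape[1]) if k != j]
        _, _, ll_red, conv_red = _irls(y, X[:, keep], offset, phi_arr)
        lrt = np.maximum(2.0 * (ll_full - ll_red), 0.0)
        p = stats.chi2.sf(lrt, df=1)
        ok = conv & conv_red
        p = np.where(ok, p, 1.0)
        fdr = adjust_bh(p)
        rows.append(pd.DataFrame({
            "gene": genes,
            "contrast": coef.removeprefix("genotype_"),
            "logFC": beta[:, j] / np.log(2.0),
            "logCPM": logcpm_avg,
            "dispersion": phi_arr,
            "p": p,
            "fdr": fdr,
            "de": fdr < alpha,
            "converged": ok,
        }))

    if joint:
        keep = [k for k, c in enumerate(coef_names)
                if c not in design.genotype_coefs]
        _, _, ll_null, conv_null = _irls(y, X[:, keep], offset, phi_arr)
        lrt = np.maximum(2.0 * (ll_full - ll_null), 0.0)
        p_joint = stats.chi2.sf(lrt, df=len(design.genotype_coefs))
        p_joint = np.where(conv & conv_null, p_joint, 1.0)
        joint_tab = pd.DataFrame(
            {"p": p_joint, "fdr": adjust_bh(p_joint)}, index=genes
        )
    else:
        joint_tab = pd.DataFrame(columns=["p", "fdr"], index=genes[:0])
    n_bad = int((~conv).sum())
    if n_bad:
        logger.warning("%d genes failed IRLS convergence (p set to 1)", n_bad)
    if rows:
        table = pd.concat(rows, ignore_index=True)
    else:
        table = pd.DataFrame(columns=[
            "gene", "contrast", "logFC", "logCPM", "dispersion", "p", "fdr",
            "de", "converged",
        ])
    return DEResult(table=table, joint=joint_tab, design=design, alpha=alpha)
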