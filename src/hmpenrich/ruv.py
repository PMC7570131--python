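"""Removal of unwanted variation from negative-control genes (RUVg).

Latent nuisance factors are estimated by factor analysis of genes believed a
priori not to respond to the biology of interest: here, the genes with the
largest joint (ANOVA-type) p-value from an initial differential-expression
fit.  The sample-side singular vectors of their row-centred log counts give
the factor column(s) W, which then enter the design matrix of a second fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts import CountMatrix


@dataclass
class LatentFactors:
    """Estimated unwanted-variation factors W (samples x k, unit-norm
    columns) and the negative-control genes they were derived from."""

    W: pd.DataFrame
    control_genes: list[str]

    @property
    def k(self) -> int:
        return self.W.shape[1]


def select_negative_controls(joint_p: pd.Series, n_controls: int = 5000) -> list[str]:
    """The ``n_controls`` genes with the largest joint-test p-value.

    ``joint_p`` is the per-gene p-value of the ANOVA-type test over all
    genotype coefficients.  Ties are broken by gene ID order.
    """
    if n_controls > len(joint_p):
        raise ValueError(
            f"n_controls={n_controls} exceeds {len(joint_p)} genes"
        )
    order = joint_p.sort_index().sort_values(ascending=False, kind="stable")
    return list(order.index[:n_controls])


def estimate_ruv_factors(m: CountMatrix, controls, k: int = 1,
                         pseudo_count: float = 1.0,
                         normalize: bool = True) -> LatentFactors:
    """Estimate k factors of unwanted variation from control-gene log counts.

    Counts are first brought to a common scale (divided by effective library
    size and rescaled to the geometric-mean library; ``normalize=False``
    skips this), log-transformed (natural log, offset ``pseudo_count``),
    row-centred, and decomposed by SVD; W is the first k sample-side singular
    vectors, each sign-fixed so its largest-magnitude coordinate is positive.
    Normalizing first matters: otherwise the leading factor is dominated by
    library-size scaling, which the model already handles through its offset,
    instead of the residual unwanted variation W is meant to capture.
    """
    controls = list(controls)
    missing = [g for g in controls if g not in m.counts.index]
    if missing:
        raise ValueError(f"control genes not in count matrix: {missing[:5]}")
    if k < 1:
        raise ValueError("k must be >= 1")
    values = m.counts.loc[controls].to_numpy(dtype=float)
    if normalize:
        eff = m.effective_lib_sizes.to_numpy(dtype=float)
        values = values / eff * np.exp(np.mean(np.log(eff)))
    logc = np.log(values + pseudo_count)
    centered = logc - logc.mean(axis=1, keepdims=True)
    # samples x genes orientation: left singular vectors live in sample space
    u, s, _ = np.linalg.svd(centered.T, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds rank {rank} of the control matrix")
    W = u[:, :k].copy()
    for col in range(k):
        if W[np.argmax(np.abs(W[:, col])), col] < 0:
            W[:, col] = -W[:, col]
    return LatentFactors(
        W=pd.DataFrame(
            W, index=m.counts.columns, columns=[f"W{j + 1}" for j in range(k)]
        ),
        control_genes=controls,
    )


def ruv_two_pass(m: CountMatrix, metadata: pd.DataFrame, k: int = 1,
                 n_controls: int = 5000, prior_df: float = 10.0,
                 grid=None, joint_only: bool = False):
    """The full two-pass protocol: initial DE fit without W, negative-control
    selection, then factor estimation.

    Returns ``(LatentFactors, initial DEResult)``.  Encoding the two passes
    as one operation prevents the easy misuse of selecting controls from a
    fit that already contains W.  ``joint_only`` skips the per-coefficient
    tests of the initial fit (control selection needs only the joint test);
    ``grid`` overrides the dispersion grid.
    """
    from .de import DesignSpec, estimate_dispersions, fit_and_test

    design0 = DesignSpec.from_metadata(metadata)
    kwargs = {} if grid is None else {"grid": grid}
    disp0 = estimate_dispersions(m, design0, prior_df=prior_df, **kwargs)
    de0 = fit_and_test(m, design0, disp0,
                       contrasts=[] if joint_only else None)
    controls = select_negative_controls(de0.joint["p"], n_controls=n_controls)
    factors = estimate_ruv_factors(m, controls, k=k)
    return factors, de0
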