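"""End-to-end orchestration: preprocess -> RUV -> DE -> enrichment -> consensus.

The stages mirror the analysis order of the study design this package
emulates: gene-level aggregation of transcript abundances, detection
filtering, TMM normalization, an initial DE fit used only to select negative
control genes, RUVg estimation of one unwanted-variation factor, the final DE
fit with W in the design, three enrichment tests per contrast, harmonic-mean
consensus with FDR control, and (optionally) the gene-label permutation null.
All randomness flows from a single top-level seed through named substreams so
stages are decoupled.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consensus import (
    ConsensusTable,
    EnrichmentState,
    leading_edge_overlap,
    permute_label_validation,
    run_enrichment,
)
from .counts import (
    CountMatrix,
    FilterRule,
    aggregate_to_genes,
    cpm,
    filter_undetected,
    read_counts_tsv,
    read_kallisto_dir,
    read_metadata,
    tmm_normalize,
    write_counts_tsv,
    write_norm_factors,
)
from .de import DesignSpec, estimate_dispersions, fit_and_test
from .enrichment import rank_genes
from .gene_sets import GeneSetCollection, map_ids, read_gmt, read_id_mapping
from .ruv import estimate_ruv_factors, select_negative_controls

logger = logging.getLogger(__name__)


def _substream(seed: int, label: str) -> np.random.Generator:
    """Named random substream derived from the top-level seed."""
    digest = sum(ord(c) * (31**i) for i, c in enumerate(label)) % (2**16)
    return np.random.default_rng(np.random.SeedSequence([seed, digest]))


@dataclass
class PipelineConfig:
    """Paths and settings for a full run; YAML-serialisable."""

    abundance_dir: str | None = None
    counts_tsv: str | None = None
    tx2gene: str | None = None
    metadata: str | None = None
    gmt_files: dict[str, str] = field(default_factory=dict)  # tag -> path
    id_mapping: str | None = None
    out_dir: str = "results"
    cpm_threshold: float = 0.66
    min_undetected: int | None = None
    ruv_k: int = 1
    n_controls: int = 5000
    prior_df: float = 10.0
    min_set_size: int = 5
    n_perm: int = 2_000
    n_rot: int = 1_999
    gsea_weight: float = 1.0
    alpha: float = 0.05
    validate_n_perm: int = 0          # 0 disables the permutation null
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def check_paths(self) -> None:
        for p in [self.abundance_dir, self.counts_tsv, self.tx2gene,
                  self.metadata, self.id_mapping, *self.gmt_files.values()]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")


@dataclass
class PipelineResult:
    counts: CountMatrix
    design: DesignSpec
    factors: "pd.DataFrame"
    de: "object"                      # DEResult of the final fit
    consensus: dict[str, ConsensusTable]
    per_method: dict[str, dict[str, pd.DataFrame]]
    state: EnrichmentState
    permutation_report: object | None = None
    manifest: dict = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def load_inputs(config: PipelineConfig):
    if config.counts_tsv:
        m = read_counts_tsv(config.counts_tsv, config.metadata)
        meta = m.samples
    elif config.abundance_dir:
        table = read_kallisto_dir(config.abundance_dir, config.tx2gene)
        meta = read_metadata(config.metadata)
        m = aggregate_to_genes(table, metadata=meta)
    else:
        raise ValueError("config must give abundance_dir or counts_tsv")
    sets = GeneSetCollection()
    for tag, path in config.gmt_files.items():
        part = read_gmt(path, tag=tag)
        sets.sets.update(part.sets)
        sets.tags.update(part.tags)
    if config.id_mapping:
        sets = map_ids(sets, read_id_mapping(config.id_mapping))
    return m, meta, sets


def run_pipeline(config: PipelineConfig,
                 inputs: tuple | None = None,
                 write_outputs: bool = True) -> PipelineResult:
    """Execute the full analysis; optionally write the TSV/JSON output tree.

    ``inputs`` may supply pre-loaded ``(CountMatrix, metadata, sets)`` to run
    on in-memory data (e.g. straight from the simulator).
    """
    if inputs is None:
        config.check_paths()
        m_raw, meta, sets = load_inputs(config)
    else:
        m_raw, meta, sets = inputs
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    # --- preprocessing -----------------------------------------------------
    rule = FilterRule(config.cpm_threshold, config.min_undetected)
    m = filter_undetected(m_raw, rule)
    if m.counts.shape[0] == 0:
        raise RuntimeError("pipeline stage 'filter' failed: no genes retained")
    m = tmm_normalize(m)
    manifest["stages"]["preprocess"] = {
        "genes_in": int(m_raw.counts.shape[0]),
        "genes_retained": int(m.counts.shape[0]),
        "lib_size_min": float(m.lib_sizes.min()),
        "lib_size_max": float(m.lib_sizes.max()),
    }
    logger.info("retained %d genes; library sizes %.0f-%.0f",
                m.counts.shape[0], m.lib_sizes.min(), m.lib_sizes.max())

    # --- initial DE fit and RUVg ------------------------------------------
    design0 = DesignSpec.from_metadata(meta)
    disp0 = estimate_dispersions(m, design0, prior_df=config.prior_df)
    de0 = fit_and_test(m, design0, disp0, alpha=config.alpha)
    n_controls = min(config.n_controls, m.counts.shape[0])
    controls = select_negative_controls(de0.joint["p"], n_controls=n_controls)
    factors = estimate_ruv_factors(m, controls, k=config.ruv_k)
    manifest["stages"]["ruv"] = {
        "k": config.ruv_k, "n_controls": n_controls,
    }

    # --- final DE fit with W ----------------------------------------------
    design = DesignSpec.from_metadata(meta, W=factors.W)
    disp = estimate_dispersions(m, design, prior_df=config.prior_df)
    de = fit_and_test(m, design, disp, alpha=config.alpha)
    contrasts = design.contrast_names()
    manifest["stages"]["de"] = {
        c: int(de.n_de(c)) for c in contrasts
    }

    # --- enrichment and consensus ------------------------------------------
    universe = list(m.counts.index)
    sets_r = sets.restrict_to_universe(universe, min_size=config.min_set_size)
    logcpm = cpm(m, log=True)
    ranked = {c: rank_genes(de, c) for c in contrasts}
    state = EnrichmentState(
        logcpm=logcpm, design=design, ranked=ranked, sets=sets_r,
        n_perm=config.n_perm, n_rot=config.n_rot,
        gsea_weight=config.gsea_weight, alpha=config.alpha,
    )
    consensus: dict[str, ConsensusTable] = {}
    per_method: dict[str, dict[str, pd.DataFrame]] = {}
    for c in contrasts:
        rng = _substream(config.seed, f"enrichment:{c}")
        consensus[c], per_method[c] = run_enrichment(state, c, rng=rng)
    manifest["stages"]["consensus"] = {
        c: int(consensus[c].n_significant()) for c in contrasts
    }

    # --- optional permutation-label null ------------------------------------
    report = None
    if config.validate_n_perm > 0:
        report = permute_label_validation(
            state, n_perm=config.validate_n_perm,
            seed=int(_substream(config.seed, "permutation").integers(2**31)),
        )
        manifest["stages"]["validation"] = {
            "n_permutations": report.n_permutations,
            "fraction_any_significant": report.fraction_any_significant(),
        }

    result = PipelineResult(
        counts=m, design=design, factors=factors.W, de=de,
        consensus=consensus, per_method=per_method, state=state,
        permutation_report=report, manifest=manifest,
    )
    if write_outputs:
        write_output_tree(result, config)
    return result


def write_output_tree(result: PipelineResult, config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_counts_tsv(result.counts, out / "filtered_counts.tsv")
    write_norm_factors(result.counts, out / "norm_factors.tsv")
    result.factors.rename_axis("sample").to_csv(out / "ruv_factors.tsv", sep="\t")
    result.de.table.to_csv(out / "de_results.tsv", sep="\t", index=False)
    dot_rows = []
    for c, cons in result.consensus.items():
        cons.table.to_csv(out / f"consensus_{c}.tsv", sep="\t")
        for mname, tab in result.per_method[c].items():
            tab.to_csv(out / f"enrichment_{mname}_{c}.tsv", sep="\t", index=False)
        overlap = leading_edge_overlap(
            result.per_method[c]["gsea"], significant_sets=cons.significant
        )
        overlap.to_csv(out / f"leading_edge_overlap_{c}.tsv", sep="\t", index=False)
        for name, row in cons.table.iterrows():
            dot_rows.append({
                "set": name, "contrast": c,
                "neglog10_hmp": -np.log10(row["hmp"]),
                "fdr_hmp": row["fdr_hmp"],
                "significant": bool(row["significant"]),
            })
    pd.DataFrame(dot_rows).to_csv(out / "consensus_dotplot.tsv", sep="\t",
                                  index=False)
    if result.permutation_report is not None:
        report = result.permutation_report
        (out / "permutation_report.json").write_text(json.dumps({
            "n_permutations": report.n_permutations,
            "seed": report.seed,
            "fraction_any_significant": report.fraction_any_significant(),
            "counts": report.counts.to_dict(orient="records"),
        }, indent=1))
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1))
    return out


# ---------------------------------------------------------------------------
# sample-level diagnostics


def pca_diagnostic(logcpm: pd.DataFrame, lib_sizes: pd.Series,
                   W: pd.DataFrame | None = None, n_components: int = 2):
    """Sample PCA of logCPM profiles and PC correlation with library size.

    Returns a dict with PC coordinates and the Pearson correlation of the
    first two PCs with log library size, before and (if ``W`` is given)
    after regressing W out of the logCPM matrix.
    """
    if logcpm.shape[1] < 3:
        raise ValueError("PCA diagnostic needs at least 3 samples")

    def _pca(mat: pd.DataFrame) -> pd.DataFrame:
        X = mat.to_numpy(dtype=float).T          # samples x genes
        X = X - X.mean(axis=0, keepdims=True)
        if np.allclose(X, 0):
            raise ValueError("constant matrix has no principal components")
        u, s, _ = np.linalg.svd(X, full_matrices=False)
        coords = u[:, :n_components] * s[:n_components]
        return pd.DataFrame(
            coords, index=mat.columns,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        )

    log_lib = np.log(lib_sizes.loc[logcpm.columns].to_numpy(dtype=float))

    def _corr(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    before = _pca(logcpm)
    out = {
        "coords_before": before,
        "corr_before": {pc: _corr(before[pc], log_lib) for pc in before},
    }
    if W is not None:
        Wm = np.column_stack([
            np.ones(logcpm.shape[1]), W.loc[logcpm.columns].to_numpy(dtype=float)
        ])
        Y = logcpm.to_numpy(dtype=float)
        beta = np.linalg.lstsq(Wm, Y.T, rcond=None)[0]
        resid = pd.DataFrame(
            (Y.T - Wm @ beta).T, index=logcpm.index, columns=logcpm.columns
        )
        after = _pca(resid)
        out["coords_after"] = after
        out["corr_after"] = {pc: _corr(after[pc], log_lib) for pc in after}
    return out


def marker_distribution(logcpm: pd.DataFrame, marker_lists: dict[str, list[str]],
                        mad_threshold: float = 2.0) -> pd.DataFrame:
    """Per-sample logCPM summaries for cell-type marker lists.

    For each marker list and sample: median and quartiles of the member
    logCPMs; a sample is flagged when its median deviates from the across-
    sample centre by more than ``mad_threshold`` MADs of the pooled marker
    logCPMs (a shift that would suggest altered cell-type proportions).
    """
    rows = []
    for cell_type, markers in marker_lists.items():
        present = [g for g in markers if g in logcpm.index]
        if not present:
            logger.info("marker list %s has no genes in matrix; skipped",
                        cell_type)
            continue
        sub = logcpm.loc[present]
        medians = sub.median(axis=0)
        centre = float(medians.median())
        pooled = sub.to_numpy().ravel()
        mad = float(np.median(np.abs(pooled - np.median(pooled))))
        scale = max(mad, 1e-8)
        for sample in logcpm.columns:
            med = float(medians[sample])
            rows.append({
                "cell_type": cell_type,
                "sample": sample,
                "n_markers": len(present),
                "median": med,
                "q25": float(sub[sample].quantile(0.25)),
                "q75": float(sub[sample].quantile(0.75)),
                "flagged": bool(abs(med - centre) > mad_threshold * scale),
            })
    return pd.DataFrame(rows)


def plot_pca(diag: dict, path, metadata: pd.DataFrame | None = None) -> None:
    """Scatter of PC1 vs PC2 (before and, when present, after adjustment)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    keys = [k for k in ("coords_before", "coords_after") if k in diag]
    fig, axes = plt.subplots(1, len(keys), figsize=(5 * len(keys), 4),
                             squeeze=False)
    for ax, key in zip(axes[0], keys):
        coords = diag[key]
        if metadata is not None and "genotype" in metadata:
            for geno, sub in coords.groupby(metadata.loc[coords.index, "genotype"]):
                ax.scatter(sub["PC1"], sub["PC2"], label=str(geno), s=25)
            ax.legend(fontsize=7)
        else:
            ax.scatter(coords["PC1"], coords["PC2"], s=25)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.set_title(key.replace("coords_", "").replace("_", " "))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
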