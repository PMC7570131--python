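"""Truth-known synthetic data emulating a four-genotype sibling RNA-seq study.

The generator produces transcript-level abundance tables (kallisto-style
``est_counts``), sample metadata, gene-set collections and a truth record, with
the statistical structure of a whole-brain bulk RNA-seq experiment on sibling
fish: four genotype groups of unequal size (wild type as reference), sex and
rearing-tank nuisance factors, a latent unwanted factor correlated with library
size, negative-binomial gene counts with a decreasing mean-dispersion trend,
and *subtle* planted signal — coordinated small log-fold-changes spread over
selected gene sets, plus a handful of large-effect individual genes.

Gene-level counts for gene ``i`` in sample ``j`` are drawn as

    y_ij ~ NB(mean = s_j * b_i * exp(x_j' beta_i + a_i w_j), dispersion = phi_i)

where ``s_j`` sets the library size, ``b_i`` is a log-normal baseline
abundance, ``x_j`` encodes genotype/sex/tank, ``w_j`` is the latent factor
(correlated with log library size) and ``phi_i`` follows the trend
``phi0 + c / mu_i``.  The gene count is then split across that gene's mature
transcripts with fixed per-gene usage weights, so transcript ``est_counts``
are fractional but sum exactly to the NB gene draw; an extra low-count
"unspliced" transcript per gene (ID suffix ``.unspliced``) carries intronic
signal that correct aggregation must discard.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GENOTYPES = ("wildtype", "eofad_het", "null_het", "trans_het")
#: contrasts of each mutant genotype against the wild-type reference
CONTRASTS = ("eofad_het", "null_het", "trans_het")

UNSPLICED_SUFFIX = ".unspliced"


class SimConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass
class PerturbedSet:
    """A gene set given a coordinated expression shift in some contrasts.

    ``logfc`` is the per-gene log2 fold change applied to a random
    ``frac_shifted`` of the set's members (same genes in every listed
    contrast); sign gives the direction of the shift.
    """

    name: str
    contrasts: tuple[str, ...] = CONTRASTS
    logfc: float = 0.3
    frac_shifted: float = 0.8


@dataclass
class SimConfig:
    n_genes: int = 12_000
    max_transcripts_per_gene: int = 3
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "wildtype": 8, "eofad_het": 6, "null_het": 4, "trans_het": 6,
        }
    )
    n_tanks: int = 3
    lib_size_range: tuple[float, float] = (0.5e6, 1.0e6)
    # log-normal baseline abundance (natural-log mean and sd of relative level)
    baseline_logmean_params: tuple[float, float] = (1.0, 1.6)
    # phi_i = asymptote + amplitude / mu_i  (mu at the geometric-mean library)
    dispersion_trend: tuple[float, float] = (0.05, 2.0)
    perturbed_sets: list[PerturbedSet] = field(default_factory=list)
    # (loading sd, fraction of genes loaded, correlation with log lib size)
    latent_factor: tuple[float, float, float] = (0.3, 0.5, 0.8)
    n_de_genes: int = 5
    de_logfc: float = 2.0
    # nuisance biology: fraction of genes with a sex / tank effect, and sd
    sex_effect: tuple[float, float] = (0.10, 0.3)
    tank_effect: tuple[float, float] = (0.10, 0.2)
    unspliced_fraction: float = 0.05
    # gene-set generation
    n_sets: int = 100
    set_size_range: tuple[int, int] = (15, 200)
    set_overlap: float | None = None
    min_ire_like_sets: int = 4
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise SimConfigError("n_genes must be positive")
        if not self.group_sizes or any(n <= 0 for n in self.group_sizes.values()):
            raise SimConfigError("all genotype groups must be non-empty")
        if set(self.group_sizes) != set(GENOTYPES):
            raise SimConfigError(f"group_sizes must cover genotypes {GENOTYPES}")
        if self.max_transcripts_per_gene < 1:
            raise SimConfigError("need at least one transcript per gene")
        lo, hi = self.lib_size_range
        if not (0 < lo <= hi):
            raise SimConfigError("lib_size_range must be positive and ordered")
        if self.dispersion_trend[0] <= 0:
            raise SimConfigError("dispersion asymptote must be > 0")
        if self.set_size_range[1] > self.n_genes:
            raise SimConfigError("set size exceeds n_genes")
        for ps in self.perturbed_sets:
            unknown = set(ps.contrasts) - set(CONTRASTS)
            if unknown:
                raise SimConfigError(f"unknown contrasts {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes.values())


@dataclass
class SimTruth:
    """Planted effects and latent structure, for downstream recovery checks."""

    de_genes: dict[str, dict[str, float]]        # contrast -> gene -> log2FC
    perturbed_sets: dict[str, dict[str, float]]  # contrast -> set -> log2FC
    w_true: pd.Series                            # latent factor per sample
    gene_means: pd.DataFrame | None = None       # genes x samples NB means
    gene_dispersions: pd.Series | None = None

    def to_json(self) -> str:
        payload = {
            "de_genes": self.de_genes,
            "perturbed_sets": self.perturbed_sets,
            "w_true": self.w_true.to_dict(),
            "gene_dispersions": (
                None if self.gene_dispersions is None
                else self.gene_dispersions.to_dict()
            ),
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        return cls(
            de_genes=d["de_genes"],
            perturbed_sets=d["perturbed_sets"],
            w_true=pd.Series(d["w_true"]),
            gene_dispersions=(
                None if d.get("gene_dispersions") is None
                else pd.Series(d["gene_dispersions"])
            ),
        )


# ---------------------------------------------------------------------------
# gene identifiers and metadata


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def make_metadata(config: SimConfig) -> pd.DataFrame:
    """Sample table with genotype, sex and tank, in fixed genotype-block order.

    Sexes alternate within genotype blocks and tanks cycle across samples, so
    both nuisance factors are roughly balanced against genotype, as in a
    sibling design where clutches are split across tanks.
    """
    rows = []
    i = 0
    for genotype in GENOTYPES:
        for _ in range(config.group_sizes[genotype]):
            rows.append(
                {
                    "sample": f"S{i + 1:02d}",
                    "genotype": genotype,
                    "sex": "female" if i % 2 == 0 else "male",
                    "tank": f"tank{(i % config.n_tanks) + 1}",
                }
            )
            i += 1
    return pd.DataFrame(rows).set_index("sample")


# ---------------------------------------------------------------------------
# gene sets


def generate_gene_sets(config: SimConfig, rng: np.random.Generator | None = None):
    """Draw a named gene-set collection over the simulated gene universe.

    Set sizes are uniform over ``config.set_size_range``.  ``set_overlap``
    controls sharing: ``None`` draws each set independently from the whole
    universe (incidental overlap only); ``0.0`` forces all sets pairwise
    disjoint; a fraction ``f`` makes each set draw ``round(f * size)`` of its
    members from the union of previously drawn sets.  Provenance tags cycle
    KEGG-like / HALLMARK-like, with the last ``min_ire_like_sets`` small sets
    tagged IRE-like (a compact family for targeted testing).
    """
    from .gene_sets import GeneSetCollection  # local import to avoid a cycle

    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    genes = np.array(_gene_ids(config.n_genes))
    lo, hi = config.set_size_range
    n_main = config.n_sets - config.min_ire_like_sets
    if n_main < 0:
        raise SimConfigError("n_sets smaller than the IRE-like family")
    sizes = rng.integers(lo, hi + 1, size=n_main).tolist()
    # IRE-like family: small sets, as for UTR-motif collections
    sizes += rng.integers(lo, min(hi, max(lo + 1, 60)) + 1,
                          size=config.min_ire_like_sets).tolist()

    sets: dict[str, list[str]] = {}
    tags: dict[str, str] = {}
    used: list[str] = []          # union of members drawn so far, in order
    used_mask = np.zeros(config.n_genes, dtype=bool)
    for k, size in enumerate(sizes):
        if size > config.n_genes:
            raise SimConfigError(f"set size {size} exceeds n_genes")
        if config.set_overlap is None:
            idx = rng.choice(config.n_genes, size=size, replace=False)
            members = genes[idx].tolist()
        else:
            n_shared = int(round(config.set_overlap * size)) if used else 0
            n_shared = min(n_shared, len(used))
            shared = (
                list(rng.choice(np.array(used), size=n_shared, replace=False))
                if n_shared else []
            )
            fresh_pool = np.flatnonzero(~used_mask)
            if size - n_shared > fresh_pool.size:
                raise SimConfigError(
                    f"cannot draw {size} genes for set {k} without replacement"
                )
            fresh = genes[
                rng.choice(fresh_pool, size=size - n_shared, replace=False)
            ].tolist()
            members = sorted(shared + fresh)
        if k < n_main:
            name = f"{'KEGG' if k % 2 == 0 else 'HALLMARK'}_SET_{k + 1:04d}"
            tags[name] = "KEGG-like" if k % 2 == 0 else "HALLMARK-like"
        else:
            name = f"IRE_SET_{k - n_main + 1:02d}"
            tags[name] = "IRE"
        sets[name] = members
        for g in members:
            gi = int(g[1:]) - 1
            if not used_mask[gi]:
                used_mask[gi] = True
                used.append(g)
    return GeneSetCollection(sets=sets, tags=tags)


# ---------------------------------------------------------------------------
# counts


@dataclass
class TranscriptTables:
    """Raw per-transcript simulation output, pre-reader."""

    est_counts: pd.DataFrame      # transcripts x samples
    lengths: pd.Series
    tx2gene: pd.Series            # transcript -> gene
    unspliced: pd.Series          # transcript -> bool


def generate_counts(config: SimConfig, gene_sets=None):
    """Simulate transcript abundances, metadata and the truth record.

    Returns ``(TranscriptTables, metadata DataFrame, SimTruth)``.  If
    ``config.perturbed_sets`` is non-empty and ``gene_sets`` is not supplied,
    the collection is generated internally from the same seed, so set
    membership is consistent between the two operations.
    """
    config.validate()
    if gene_sets is None and config.perturbed_sets:
        gene_sets = generate_gene_sets(config)
    if config.perturbed_sets and gene_sets is not None:
        missing = [p.name for p in config.perturbed_sets
                   if p.name not in gene_sets.sets]
        if missing:
            raise SimConfigError(f"perturbed sets not in collection: {missing}")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 29]))
    meta = make_metadata(config)
    n, g = config.n_samples, config.n_genes
    genes = _gene_ids(g)
    gene_pos = {gene: i for i, gene in enumerate(genes)}

    # baseline relative abundances and target library sizes
    mu_log, sd_log = config.baseline_logmean_params
    baseline = rng.lognormal(mu_log, sd_log, size=g)
    baseline /= baseline.sum()
    lib_targets = rng.uniform(*config.lib_size_range, size=n)

    # latent factor, correlated with log library size
    load_sd, load_frac, rho = config.latent_factor
    z_lib = np.log(lib_targets)
    z_lib = (z_lib - z_lib.mean()) / max(z_lib.std(), 1e-12)
    noise = rng.standard_normal(n)
    noise -= noise.mean()
    noise /= max(noise.std(), 1e-12)
    w = rho * z_lib + np.sqrt(max(1.0 - rho**2, 0.0)) * noise
    loadings = np.where(
        rng.random(g) < load_frac, rng.normal(0.0, load_sd, size=g), 0.0
    )
    if load_sd == 0:
        loadings[:] = 0.0

    # per-gene design effects (natural-log scale), columns = contrasts
    beta = {c: np.zeros(g) for c in CONTRASTS}
    truth_de: dict[str, dict[str, float]] = {c: {} for c in CONTRASTS}
    de_pool = rng.choice(g, size=min(config.n_de_genes, g), replace=False)
    for gi in de_pool:
        contrast = CONTRASTS[int(rng.integers(len(CONTRASTS)))]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        lfc = sign * config.de_logfc
        beta[contrast][gi] += lfc * np.log(2.0)
        truth_de[contrast][genes[gi]] = lfc

    truth_sets: dict[str, dict[str, float]] = {c: {} for c in CONTRASTS}
    for ps in config.perturbed_sets:
        members = gene_sets.sets[ps.name]
        k = max(1, int(round(ps.frac_shifted * len(members))))
        chosen = rng.choice(len(members), size=k, replace=False)
        idx = [gene_pos[members[i]] for i in chosen]
        for contrast in ps.contrasts:
            beta[contrast][idx] += ps.logfc * np.log(2.0)
            truth_sets[contrast][ps.name] = ps.logfc

    frac_sex, sd_sex = config.sex_effect
    sex_beta = np.where(rng.random(g) < frac_sex,
                        rng.normal(0.0, sd_sex, size=g), 0.0)
    frac_tank, sd_tank = config.tank_effect
    tank_beta = np.where(
        rng.random((g, config.n_tanks - 1)) < frac_tank,
        rng.normal(0.0, sd_tank, size=(g, config.n_tanks - 1)), 0.0,
    ) if config.n_tanks > 1 else np.zeros((g, 0))

    # per-sample per-gene NB means
    eta = np.log(baseline)[:, None] + np.log(lib_targets)[None, :]
    for j, (sample, row) in enumerate(meta.iterrows()):
        if row["genotype"] != "wildtype":
            eta[:, j] += beta[row["genotype"]]
        if row["sex"] == "male":
            eta[:, j] += sex_beta
        tank_idx = int(row["tank"][4:]) - 1
        if tank_idx > 0:
            eta[:, j] += tank_beta[:, tank_idx - 1]
        eta[:, j] += loadings * w[j]
    mu = np.exp(eta)

    asymptote, amplitude = config.dispersion_trend
    mu_ref = baseline * np.exp(np.log(lib_targets).mean())
    phi = asymptote + amplitude / np.maximum(mu_ref, 1e-8)

    size = 1.0 / phi
    y = rng.negative_binomial(size[:, None], size[:, None] / (size[:, None] + mu))
    y = y.astype(float)

    # split gene counts across mature transcripts with fixed usage weights
    n_tx = rng.integers(1, config.max_transcripts_per_gene + 1, size=g)
    tx_ids, tx_gene, tx_unspliced, tx_rows, tx_lengths = [], [], [], [], []
    for gi, gene in enumerate(genes):
        usage = rng.dirichlet(np.ones(n_tx[gi]) * 2.0)
        for t in range(n_tx[gi]):
            tx_ids.append(f"{gene}.t{t + 1}")
            tx_gene.append(gene)
            tx_unspliced.append(False)
            tx_rows.append(y[gi] * usage[t])
            tx_lengths.append(int(rng.integers(500, 5001)))
        # intron-retaining transcript: small Poisson flux, excluded from truth
        tx_ids.append(f"{gene}{UNSPLICED_SUFFIX}")
        tx_gene.append(gene)
        tx_unspliced.append(True)
        tx_rows.append(rng.poisson(config.unspliced_fraction * mu[gi]).astype(float))
        tx_lengths.append(int(rng.integers(2000, 10001)))

    est = pd.DataFrame(np.vstack(tx_rows), index=tx_ids, columns=meta.index)
    tables = TranscriptTables(
        est_counts=est,
        lengths=pd.Series(tx_lengths, index=tx_ids, name="length"),
        tx2gene=pd.Series(tx_gene, index=tx_ids, name="gene_id"),
        unspliced=pd.Series(tx_unspliced, index=tx_ids, name="unspliced"),
    )
    truth = SimTruth(
        de_genes=truth_de,
        perturbed_sets=truth_sets,
        w_true=pd.Series(w, index=meta.index, name="w_true"),
        gene_means=pd.DataFrame(mu, index=genes, columns=meta.index),
        gene_dispersions=pd.Series(phi, index=genes, name="dispersion"),
    )
    return tables, meta, truth


# ---------------------------------------------------------------------------
# fixture I/O


def write_fixture(dir_path, tables: TranscriptTables, meta: pd.DataFrame,
                  gene_sets=None, truth: SimTruth | None = None) -> Path:
    """Write a kallisto-style fixture tree.

    Layout: ``abundance/<sample>/abundance.tsv`` (target_id, length,
    eff_length, est_counts, tpm), ``tx2gene.tsv``, ``metadata.tsv``,
    ``gene_sets.gmt`` and ``truth.json``.  Round-trips through
    :mod:`hmpenrich.counts` readers.
    """
    root = Path(dir_path)
    try:
        root.mkdir(parents=True, exist_ok=True)
        eff = np.maximum(tables.lengths.to_numpy(dtype=float) - 200.0, 50.0)
        for sample in meta.index:
            sdir = root / "abundance" / sample
            sdir.mkdir(parents=True, exist_ok=True)
            counts = tables.est_counts[sample].to_numpy()
            rate = counts / eff
            tpm = rate / rate.sum() * 1e6 if rate.sum() > 0 else rate
            pd.DataFrame(
                {
                    "target_id": tables.est_counts.index,
                    "length": tables.lengths.to_numpy(),
                    "eff_length": eff,
                    "est_counts": counts,
                    "tpm": tpm,
                }
            ).to_csv(sdir / "abundance.tsv", sep="\t", index=False)
        tables.tx2gene.rename_axis("transcript_id").reset_index().to_csv(
            root / "tx2gene.tsv", sep="\t", index=False
        )
        meta.reset_index().to_csv(root / "metadata.tsv", sep="\t", index=False)
        if gene_sets is not None:
            from .gene_sets import write_gmt

            write_gmt(gene_sets, root / "gene_sets.gmt")
        if truth is not None:
            (root / "truth.json").write_text(truth.to_json())
    except OSError as exc:
        raise OSError(f"failed writing fixture under {root}: {exc}") from exc
    return root
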