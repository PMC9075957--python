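"""Synthetic reciprocal-cross, intercross, and single-cell data with ground truth.

Emulates the statistical structure of a reciprocal F1 cross of two inbred
lines (L and S) phenotyped on high/low-fat diets:

* allelic read counts per gene follow a beta-binomial whose mean bias is 0.5
  for biallelic genes and cross-dependent for planted imprinted genes;
* total expression follows a negative binomial with multiplicative cross
  effects for planted DE genes and log-linear coupling of DE genes to their
  planted upstream ASE partner;
* an advanced intercross with linked markers, ordered maternal|paternal
  genotypes, and phenotypes carrying planted imprinting-by-imprinting
  epistasis;
* clustered cells along a marker gradient for the single-cell statistics.

Every generator is deterministic under its seed, and the planted truth is
carried alongside the data so parameter-recovery and error-rate tests have
an exact reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd

__all__ = [
    "GroundTruth",
    "AllelicCounts",
    "make_design",
    "simulate_allelic_counts",
    "simulate_expression",
    "simulate_intercross",
    "simulate_cells",
    "make_cluster_profiles",
]

CROSSES = ("LxS", "SxL")  # maternal parent listed first
SEXES = ("F", "M")
DIETS = ("HF", "LF")

# Cohort structure of the reciprocal-cross experiment this generator emulates:
# 2 crosses x 2 sexes x 2 diets x 12 animals = 96 F1 animals, 48 per cross.
DEFAULT_N_PER_CELL = 12
# Advanced-intercross cohort size used for epistasis replication.
DEFAULT_F16_ANIMALS = 1002


@dataclass
class GroundTruth:
    """Planted signal for a simulation run.

    ase_genes maps gene -> {"LxS": mean L_bias, "SxL": mean L_bias}.
    de_genes maps gene -> log2 fold change (SxL over LxS).
    edges are (ase_gene, de_gene, coupling) triples: the DE gene's log mean
    moves ``coupling`` log-units per SD of its partner's realized log
    expression.
    epistatic_triples are (ase_locus, de_locus, phenotype, beta3) with the
    interaction effect in phenotype-SD units.
    """

    ase_genes: dict = field(default_factory=dict)
    de_genes: dict = field(default_factory=dict)
    edges: list = field(default_factory=list)
    epistatic_triples: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for ase_gene, _de_gene, coupling in self.edges:
            if ase_gene not in self.ase_genes:
                raise ValueError(f"edge source {ase_gene!r} is not a planted ASE gene")
            if not np.isfinite(coupling):
                raise ValueError("coupling coefficients must be finite")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


@dataclass
class AllelicCounts:
    """Paired L-allele / S-allele count matrices (genes x samples)."""

    L: pd.DataFrame
    S: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.L.index.equals(self.S.index) or not self.L.columns.equals(self.S.columns):
            raise ValueError("L and S matrices must share genes and samples")
        if (self.L.values < 0).any() or (self.S.values < 0).any():
            raise ValueError("allelic counts must be non-negative")

    @property
    def totals(self) -> pd.DataFrame:
        return self.L + self.S


def make_design(n_per_cell: int, generation: str = "F1") -> pd.DataFrame:
    """Balanced factorial sample design for one generation.

    For the reciprocal generations (F1, F2) every (cross, sex, diet) cell
    receives ``n_per_cell`` animals in a deterministic order; F0 enumerates
    the two parental lines and F16 only sex x diet (cross is undefined
    outside the reciprocal structure).
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be a positive integer")
    if generation in ("F1", "F2"):
        cells = [(c, s, d) for c in CROSSES for s in SEXES for d in DIETS]
    elif generation == "F0":
        cells = [(line, s, d) for line in ("LL", "SS") for s in SEXES for d in DIETS]
    elif generation == "F16":
        cells = [(None, s, d) for s in SEXES for d in DIETS]
    else:
        raise ValueError(f"unknown generation {generation!r}")
    rows = []
    for cross, sex, diet in cells:
        for k in range(n_per_cell):
            rows.append(
                {
                    "sample_id": f"{generation}_{cross or 'NA'}_{sex}_{diet}_{k + 1:02d}",
                    "generation": generation,
                    "cross": cross,
                    "sex": sex,
                    "diet": diet,
                }
            )
    design = pd.DataFrame(rows)
    if design["sample_id"].duplicated().any():
        raise ValueError("sample ids must be unique")
    return design


def _nb_draw(rng, mean, dispersion, size):
    """Negative binomial with variance mean + dispersion * mean^2 (Poisson at 0)."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    return rng.poisson(rng.gamma(shape, mean / shape))


def simulate_allelic_counts(
    design: pd.DataFrame,
    truth: GroundTruth,
    genes,
    depth_mean: float = 100.0,
    depth_dispersion: float = 0.1,
    dispersion_rho: float = 0.01,
    seed: int = 0,
) -> AllelicCounts:
    """Draw L/S allelic counts with beta-binomial bias.

    Total depth per gene x sample is negative binomial with mean
    ``depth_mean``; the L count is beta-binomial with mean bias mu (0.5 for
    biallelic genes, the planted per-cross mean for imprinted genes) and
    dispersion rho, parameterized as alpha = mu (1 - rho) / rho,
    beta = (1 - mu)(1 - rho) / rho so that rho = 1 / (1 + alpha + beta).
    """
    if not 0 < dispersion_rho < 1:
        raise ValueError("dispersion_rho must lie in (0, 1)")
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    genes = list(genes)
    gene_set = set(genes)
    for g in truth.ase_genes:
        if g not in gene_set:
            raise ValueError(f"truth references unknown gene {g!r}")
    rng = np.random.default_rng(seed)
    n_genes, n_samples = len(genes), len(design)

    mu = np.full((n_genes, n_samples), 0.5)
    cross = design["cross"].to_numpy()
    for i, g in enumerate(genes):
        if g in truth.ase_genes:
            per_cross = truth.ase_genes[g]
            for c in CROSSES:
                mu[i, cross == c] = per_cross[c]

    totals = _nb_draw(rng, depth_mean, depth_dispersion, (n_genes, n_samples))
    a = mu * (1.0 - dispersion_rho) / dispersion_rho
    b = (1.0 - mu) * (1.0 - dispersion_rho) / dispersion_rho
    p = rng.beta(a, b)
    lcounts = rng.binomial(totals, p)
    sample_ids = design["sample_id"].tolist()
    L = pd.DataFrame(lcounts, index=genes, columns=sample_ids)
    S = pd.DataFrame(totals - lcounts, index=genes, columns=sample_ids)
    return AllelicCounts(L=L, S=S, design=design.copy())


def simulate_expression(
    design: pd.DataFrame,
    truth: GroundTruth,
    genes,
    baseline_mean: float = 500.0,
    nb_dispersion: float = 0.05,
    sex_log2fc: float = 0.0,
    diet_log2fc: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Negative-binomial total-expression counts (genes x samples).

    Planted DE genes split their cross effect symmetrically: the SxL mean is
    baseline * 2^(lfc/2) and the LxS mean baseline * 2^(-lfc/2), so the
    recovered fold change is 2^lfc.  Genes named as edge targets have their
    log mean shifted by coupling * z, where z is the standardized realized
    log1p expression of the upstream ASE partner, producing the ASE -> DE
    co-expression the network stage is built to detect.
    """
    if baseline_mean <= 0:
        raise ValueError("baseline_mean must be positive")
    if nb_dispersion < 0:
        raise ValueError("nb_dispersion must be non-negative")
    genes = list(genes)
    gene_set = set(genes)
    for g in list(truth.de_genes) + list(truth.ase_genes):
        if g not in gene_set:
            raise ValueError(f"truth references unknown gene {g!r}")
    rng = np.random.default_rng(seed)
    n_samples = len(design)
    cross_sign = np.where(design["cross"].to_numpy() == "SxL", 0.5, -0.5)
    sex_sign = np.where(design["sex"].to_numpy() == "M", 0.5, -0.5)
    diet_sign = np.where(design["diet"].to_numpy() == "HF", 0.5, -0.5)
    ln2 = np.log(2.0)

    counts = {}
    # ASE partners are realized first so edge targets can couple to them.
    order = [g for g in genes if g in truth.ase_genes]
    order += [g for g in genes if g not in truth.ase_genes]
    realized_z = {}
    targets = {}
    for ase_gene, de_gene, coupling in truth.edges:
        targets.setdefault(de_gene, []).append((ase_gene, coupling))
    for g in order:
        log_mean = np.full(n_samples, np.log(baseline_mean))
        log_mean += ln2 * sex_log2fc * sex_sign + ln2 * diet_log2fc * diet_sign
        if g in truth.de_genes:
            log_mean += ln2 * truth.de_genes[g] * cross_sign
        for ase_gene, coupling in targets.get(g, []):
            log_mean += coupling * realized_z[ase_gene]
        y = _nb_draw(rng, np.exp(log_mean), nb_dispersion, (n_samples,))
        counts[g] = y
        if g in truth.ase_genes:
            z = np.log1p(y.astype(float))
            sd = z.std()
            realized_z[g] = (z - z.mean()) / sd if sd > 0 else np.zeros(n_samples)
    expr = pd.DataFrame(
        np.vstack([counts[g] for g in genes]),
        index=genes,
        columns=design["sample_id"].tolist(),
    )
    return expr


def _imprinting_score_codes(maternal, paternal):
    het = maternal != paternal
    return np.where(het, np.where(maternal == "L", 1, -1), 0)


def simulate_intercross(
    n_animals: int = DEFAULT_F16_ANIMALS,
    markers=None,
    truth: GroundTruth | None = None,
    ld_decay: float = 0.2,
    noise_sd: float = 1.0,
    sex_effect: float = 0.25,
    diet_effect: float = 0.25,
    sexdiet_effect: float = 0.1,
    seed: int = 0,
):
    """Linked intercross genotypes plus phenotypes with planted epistasis.

    Each parental haplotype is a first-order Markov chain along every
    chromosome: the switch probability between adjacent markers is
    0.5 (1 - exp(-2 ld_decay d)) for distance d in Mb, which behaves like a
    per-megabase switch rate ld_decay at short range and saturates at 0.5
    (independence) as ld_decay -> infinity.  Genotypes are ordered
    maternal|paternal strings in {LL, LS, SL, SS}.  Phenotypes are
    sex + diet + sex:diet + beta3 * score_A * score_B + Gaussian noise, with
    effects in units of the noise SD.
    """
    if n_animals < 10:
        raise ValueError("n_animals must be at least 10")
    if markers is None:
        markers = [("1", 3_000_000 + 2_000_000 * i) for i in range(20)]
    truth = truth or GroundTruth()
    marker_df = pd.DataFrame(markers, columns=["chrom", "pos"])
    marker_df["chrom"] = marker_df["chrom"].astype(str)
    for chrom, sub in marker_df.groupby("chrom"):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"marker positions on chromosome {chrom} must strictly increase")
    marker_ids = [f"m_{c}_{p}" for c, p in zip(marker_df["chrom"], marker_df["pos"])]

    rng = np.random.default_rng(seed)
    haplos = {}
    for parent in ("mat", "pat"):
        alleles = np.empty((n_animals, len(marker_df)), dtype="<U1")
        for chrom, sub in marker_df.groupby("chrom", sort=False):
            idx = sub.index.to_numpy()
            pos_mb = sub["pos"].to_numpy() / 1e6
            state = rng.random(n_animals) < 0.5
            alleles[:, idx[0]] = np.where(state, "L", "S")
            for j in range(1, idx.size):
                d = pos_mb[j] - pos_mb[j - 1]
                p_switch = 0.5 * (1.0 - np.exp(-2.0 * ld_decay * d))
                flip = rng.random(n_animals) < p_switch
                state = state ^ flip
                alleles[:, idx[j]] = np.where(state, "L", "S")
        haplos[parent] = alleles

    genotypes = pd.DataFrame(
        np.char.add(haplos["mat"], haplos["pat"]),
        index=[f"F16_{i + 1:04d}" for i in range(n_animals)],
        columns=marker_ids,
    )

    sex = rng.choice(SEXES, size=n_animals)
    diet = rng.choice(DIETS, size=n_animals)
    sex_sign = np.where(sex == "M", 0.5, -0.5)
    diet_sign = np.where(diet == "HF", 0.5, -0.5)
    base = (
        sex_effect * sex_sign
        + diet_effect * diet_sign
        + sexdiet_effect * sex_sign * diet_sign
    ) * noise_sd

    pheno_names = sorted({t[2] for t in truth.epistatic_triples}) or ["phenotype"]
    pheno = pd.DataFrame(index=genotypes.index, columns=pheno_names, dtype=float)
    for name in pheno_names:
        y = base + rng.normal(0.0, noise_sd, n_animals)
        for ase_locus, de_locus, pname, beta3 in truth.epistatic_triples:
            if pname != name:
                continue
            for locus in (ase_locus, de_locus):
                if locus not in genotypes.columns:
                    raise ValueError(f"epistatic locus {locus!r} not among simulated markers")
            score_a = _imprinting_score_codes(
                haplos["mat"][:, marker_ids.index(ase_locus)],
                haplos["pat"][:, marker_ids.index(ase_locus)],
            )
            score_b = _imprinting_score_codes(
                haplos["mat"][:, marker_ids.index(de_locus)],
                haplos["pat"][:, marker_ids.index(de_locus)],
            )
            y = y + beta3 * noise_sd * score_a * score_b
        pheno[name] = y
    pheno.insert(0, "sex", sex)
    pheno.insert(1, "diet", diet)
    marker_df.index = marker_ids
    return genotypes, pheno, marker_df


def make_cluster_profiles(
    n_clusters: int = 3,
    n_genes: int = 100,
    marker_gene: str = "marker",
    marker_max: float = 10.0,
    base_mean: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cluster gene mean table with a monotone marker gradient.

    The marker's mean rises linearly from 0 in the first cluster to
    ``marker_max`` in the last, mimicking a differentiation marker whose
    expression increases along an ordered trajectory; background genes share
    a flat mean across clusters.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [marker_gene] + [f"bg{i:04d}" for i in range(n_genes - 1)]
    base = rng.gamma(2.0, base_mean / 2.0, n_genes - 1)
    profiles = pd.DataFrame(
        np.tile(base, (n_clusters, 1)),
        index=[f"cluster{i}" for i in range(n_clusters)],
        columns=gene_ids[1:],
    )
    gradient = np.linspace(0.0, marker_max, n_clusters)
    profiles.insert(0, marker_gene, gradient)
    return profiles


def simulate_cells(
    n_cells: int,
    cluster_profiles: pd.DataFrame,
    proportions=None,
    seed: int = 0,
):
    """Poisson counts per cell drawn from its cluster's mean profile.

    Returns (cell x gene count DataFrame, cluster label Series).  Cluster
    membership is drawn from ``proportions`` (uniform by default) so cluster
    sizes are realistic rather than exactly balanced.
    """
    if cluster_profiles.shape[0] < 2:
        raise ValueError("at least two clusters are required")
    if cluster_profiles.size == 0:
        raise ValueError("empty profile table")
    if (cluster_profiles.values < 0).any():
        raise ValueError("profiles must be non-negative")
    rng = np.random.default_rng(seed)
    k = cluster_profiles.shape[0]
    proportions = np.full(k, 1.0 / k) if proportions is None else np.asarray(proportions, float)
    labels_idx = rng.choice(k, size=n_cells, p=proportions / proportions.sum())
    means = cluster_profiles.to_numpy()[labels_idx]
    counts = rng.poisson(means)
    cells = [f"cell{i:05d}" for i in range(n_cells)]
    matrix = pd.DataFrame(counts, index=cells, columns=cluster_profiles.columns)
    labels = pd.Series(cluster_profiles.index.to_numpy()[labels_idx], index=cells, name="cluster")
    return matrix, labels
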