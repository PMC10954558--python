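"""Seeded synthetic "village" data generator.

A village is a pooled snRNA-seq library in which tissue from ~20 donors is
processed as a single sample and the donor of origin of each nucleus is
recovered computationally from transcribed SNPs.  The generator emulates the
statistical structure the downstream analysis assumes:

* ~20-donor pools, every donor contributing nuclei of every cell type;
* negative-binomial UMI counts with a log-linear planted-factor effect, so
  that cross-cell-type latent programs exist by construction;
* donor program scores that decline with age and carry a case-status
  deficit;
* cross-donor droplet doublets that mix two donors' expected expression
  profiles 50/50 and pool their SNP evidence;
* aberrant ("outlier") donors whose expression profile is multiplicatively
  perturbed on a fraction of genes without changing library size;
* paralog gene families whose UMIs are consistently co-ambiguous.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmwrite

__all__ = [
    "DonorProfile",
    "ProgramSpec",
    "OutlierSpec",
    "VillageConfig",
    "VillageSimulation",
    "make_donors",
    "plant_programs",
    "simulate_village",
    "simulate_factor_matrix",
    "simulate_umi_records",
    "write_village",
]


@dataclass
class DonorProfile:
    """A single brain donor: covariates, genotype and planted program scores.

    ``genotype`` holds alt-allele dosages in {0, 1, 2} over the SNP panel.
    ``program_scores`` is filled by :func:`plant_programs`.
    """

    donor_id: str
    age: float
    sex: str  # "F" | "M"
    status: str  # "case" | "control"
    genotype: np.ndarray
    program_scores: np.ndarray | None = None


@dataclass
class ProgramSpec:
    """Specification of planted cross-cell-type latent programs.

    Each of the ``n_factors`` programs has, per cell type, a gene-loading
    vector (``loadings_per_celltype[ct]`` has shape (n_genes, n_factors)),
    and donor-level score structure: a linear age slope (score units per
    year), an additive case shift, and Gaussian score noise.
    """

    n_factors: int
    loadings_per_celltype: dict[str, np.ndarray]
    age_slope: np.ndarray | float = 0.0
    case_shift: np.ndarray | float = 0.0
    score_noise_sd: np.ndarray | float = 0.0
    baseline: np.ndarray | float = 0.0

    def __post_init__(self):
        if self.n_factors < 1:
            raise ValueError("empty program spec")
        k = self.n_factors
        for name in ("age_slope", "case_shift", "score_noise_sd", "baseline"):
            v = np.broadcast_to(np.asarray(getattr(self, name), float), (k,)).copy()
            setattr(self, name, v)
        if np.any(self.score_noise_sd < 0):
            raise ValueError("score noise sd must be non-negative")
        for ct, L in self.loadings_per_celltype.items():
            L = np.asarray(L, float)
            if L.ndim != 2 or L.shape[1] != k:
                raise ValueError(
                    f"loadings for {ct!r} must have shape (n_genes, {k})"
                )
            self.loadings_per_celltype[ct] = L
        if self.loadings_per_celltype:
            stacked = np.vstack(list(self.loadings_per_celltype.values()))
            if np.any(np.all(stacked == 0, axis=0)):
                raise ValueError("every factor needs a nonzero loading somewhere")


@dataclass
class OutlierSpec:
    """Planted aberrant donors: a multiplicative log-normal perturbation of a
    random fraction of genes, shared across that donor's nuclei and cell
    types.  Library size is preserved because per-nucleus gene proportions
    are renormalized after the perturbation."""

    n_outliers: int = 0
    gene_fraction: float = 0.3
    log_sd: float = 1.0


@dataclass
class VillageConfig:
    """Settings for :func:`simulate_village`.

    The defaults define the package's reference study conditions: two
    20-donor villages (40 donors), three cell types, negative-binomial
    counts, a 5% doublet rate and a 200-SNP common-variant panel.
    """

    n_donors: int = 40
    village_size: int = 20
    cell_types: tuple[str, ...] = ("glutamatergic", "gabaergic", "astrocyte")
    n_genes: int = 300
    nuclei_per_donor_per_type: int = 20
    mean_umis_per_nucleus: float = 400.0
    depth_log_sd: float = 0.3
    dispersion: float = 10.0  # NB theta; np.inf gives the Poisson limit
    doublet_rate: float = 0.05
    n_snps: int = 200
    snp_maf_range: tuple[float, float] = (0.1, 0.5)
    snp_error_rate: float = 0.01
    snp_obs_per_nucleus: int = 60
    age_range: tuple[float, float] = (22.0, 97.0)
    program: ProgramSpec | None = None
    outliers: OutlierSpec = field(default_factory=OutlierSpec)


@dataclass
class VillageSimulation:
    """Full synthetic ground truth for one simulated study."""

    config: VillageConfig
    donors: list[DonorProfile]
    villages: list[list[str]]
    gene_ids: list[str]
    counts: sparse.csr_matrix  # genes x nuclei
    nuclei: pd.DataFrame  # barcode, village, cell_type, donor, donor2, is_doublet
    genotypes: pd.DataFrame  # donors x SNPs, dosages
    snp_obs: pd.DataFrame  # barcode, snp_id, allele, count
    outlier_truth: list[str]
    metagene_truth: list[tuple[str, ...]] = field(default_factory=list)
    baseline_log_weights: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def cell_to_donor(self) -> pd.Series:
        return self.nuclei.set_index("barcode")["donor"]

    @property
    def cell_to_type(self) -> pd.Series:
        return self.nuclei.set_index("barcode")["cell_type"]


def make_donors(config: VillageConfig, rng: np.random.Generator) -> list[DonorProfile]:
    """Draw donor covariates and genotypes.

    Ages are uniform on ``config.age_range``; sex and case-control status
    alternate so each village is balanced; SNP dosages are binomial(2, MAF)
    with MAF uniform on ``config.snp_maf_range`` (independent common sites).
    """
    lo, hi = config.age_range
    ages = rng.uniform(lo, hi, size=config.n_donors)
    mafs = rng.uniform(*config.snp_maf_range, size=config.n_snps)
    donors = []
    for i in range(config.n_donors):
        genotype = rng.binomial(2, mafs)
        donors.append(
            DonorProfile(
                donor_id=f"donor{i:03d}",
                age=float(ages[i]),
                sex="F" if i % 2 == 0 else "M",
                status="case" if (i // 2) % 2 == 0 else "control",
                genotype=genotype.astype(np.int8),
            )
        )
    return donors


def plant_programs(
    donors: Sequence[DonorProfile], spec: ProgramSpec, seed: int
) -> list[DonorProfile]:
    """Fill per-donor program scores from the spec's linear covariate model.

    score_k(donor) = baseline_k + age_slope_k * (age - mean age)
                     + case_shift_k * 1[case] + Normal(0, noise_sd_k)
    """
    rng = np.random.default_rng(seed)
    ages = np.array([d.age for d in donors])
    mean_age = ages.mean()
    out = []
    for d in donors:
        noise = rng.normal(0.0, 1.0, size=spec.n_factors) * spec.score_noise_sd
        scores = (
            spec.baseline
            + spec.age_slope * (d.age - mean_age)
            + spec.case_shift * (1.0 if d.status == "case" else 0.0)
            + noise
        )
        out.append(replace(d, program_scores=scores))
    return out


def _nucleus_log_weights(
    base_log_w: np.ndarray,
    donor: DonorProfile,
    cell_type: str,
    program: ProgramSpec | None,
    outlier_delta: np.ndarray | None,
) -> np.ndarray:
    lw = base_log_w.copy()
    if program is not None and donor.program_scores is not None:
        L = program.loadings_per_celltype.get(cell_type)
        if L is not None:
            lw = lw + L @ donor.program_scores
    if outlier_delta is not None:
        lw = lw + outlier_delta
    return lw


def _proportions(log_w: np.ndarray) -> np.ndarray:
    w = np.exp(log_w - log_w.max())
    return w / w.sum()


def simulate_village(config: VillageConfig, seed: int) -> VillageSimulation:
    """Generate a fully seeded synthetic pooled-donor study.

    Per-nucleus counts are negative binomial with log-mean
    baseline(gene, cell type) + sum_k score_k(donor) * loading_k(gene, ct);
    doublets mix two donors' expected profiles 50/50 and pool their SNP
    evidence; per-SNP allele observations are drawn from the donor genotype
    with error rate epsilon.
    """
    if not 0.0 <= config.doublet_rate < 1.0:
        raise ValueError("doublet_rate must be in [0, 1)")
    if config.village_size < 1 or config.village_size > config.n_donors:
        raise ValueError("village_size must be in [1, n_donors]")
    if config.n_genes < 1:
        raise ValueError("need at least one gene")

    rng = np.random.default_rng(seed)
    donors = make_donors(config, rng)
    if config.program is not None:
        donors = plant_programs(
            donors, config.program, seed=int(rng.integers(0, 2**31 - 1))
        )
    donor_by_id = {d.donor_id: d for d in donors}

    villages = [
        [d.donor_id for d in donors[i : i + config.village_size]]
        for i in range(0, config.n_donors, config.village_size)
    ]

    gene_ids = [f"GENE{g:04d}" for g in range(config.n_genes)]
    snp_ids = [f"snp{s:04d}" for s in range(config.n_snps)]

    # per cell type baseline gene weights (log scale)
    base_log_w = {
        ct: rng.normal(0.0, 1.0, size=config.n_genes) for ct in config.cell_types
    }

    # planted outliers: shared per-donor gene perturbation
    outlier_ids: list[str] = []
    outlier_delta: dict[str, np.ndarray] = {}
    if config.outliers.n_outliers > 0:
        idx = rng.choice(config.n_donors, size=config.outliers.n_outliers, replace=False)
        for i in sorted(idx):
            d = donors[i]
            outlier_ids.append(d.donor_id)
            n_hit = int(round(config.outliers.gene_fraction * config.n_genes))
            hit = rng.choice(config.n_genes, size=n_hit, replace=False)
            delta = np.zeros(config.n_genes)
            delta[hit] = rng.normal(0.0, config.outliers.log_sd, size=n_hit)
            outlier_delta[d.donor_id] = delta

    theta = config.dispersion
    eps = config.snp_error_rate

    barcodes: list[str] = []
    meta_rows: list[tuple] = []
    count_cols: list[np.ndarray] = []
    obs_rows: list[tuple] = []
    nuc_idx = 0

    for v, vill in enumerate(villages):
        for donor_id in vill:
            donor = donor_by_id[donor_id]
            for ct in config.cell_types:
                for _ in range(config.nuclei_per_donor_per_type):
                    barcode = f"BC{nuc_idx:07d}"
                    nuc_idx += 1
                    is_doublet = rng.random() < config.doublet_rate
                    partner = None
                    lw = _nucleus_log_weights(
                        base_log_w[ct], donor, ct, config.program,
                        outlier_delta.get(donor_id),
                    )
                    p = _proportions(lw)
                    if is_doublet:
                        partner_id = vill[int(rng.integers(len(vill)))]
                        partner = donor_by_id[partner_id]
                        lw2 = _nucleus_log_weights(
                            base_log_w[ct], partner, ct, config.program,
                            outlier_delta.get(partner_id),
                        )
                        p = 0.5 * (p + _proportions(lw2))
                    depth = rng.lognormal(
                        np.log(config.mean_umis_per_nucleus)
                        - 0.5 * config.depth_log_sd**2,
                        config.depth_log_sd,
                    )
                    mu = depth * p
                    if np.isinf(theta):
                        counts = rng.poisson(mu)
                    else:
                        counts = rng.negative_binomial(theta, theta / (theta + mu))
                    count_cols.append(counts.astype(np.int64))

                    # transcribed-SNP allele observations (one read per site)
                    sites = rng.choice(
                        config.n_snps, size=min(config.snp_obs_per_nucleus,
                                                config.n_snps), replace=False,
                    )
                    for s in np.sort(sites):
                        src = donor
                        if is_doublet and rng.random() < 0.5:
                            src = partner
                        g = src.genotype[s]
                        p_alt = (1.0 - 2.0 * eps) * g / 2.0 + eps
                        allele = "alt" if rng.random() < p_alt else "ref"
                        obs_rows.append((barcode, snp_ids[s], allele, 1))

                    barcodes.append(barcode)
                    meta_rows.append(
                        (barcode, v, ct, donor_id,
                         partner.donor_id if partner is not None else "",
                         bool(is_doublet))
                    )

    counts = sparse.csr_matrix(
        np.column_stack(count_cols) if count_cols else
        np.zeros((config.n_genes, 0), dtype=np.int64)
    )
    nuclei = pd.DataFrame(
        meta_rows,
        columns=["barcode", "village", "cell_type", "donor", "donor2", "is_doublet"],
    )
    genotypes = pd.DataFrame(
        np.vstack([d.genotype for d in donors]),
        index=[d.donor_id for d in donors],
        columns=snp_ids,
        dtype=np.int8,
    )
    snp_obs = pd.DataFrame(
        obs_rows, columns=["barcode", "snp_id", "allele", "count"]
    )
    return VillageSimulation(
        config=config,
        donors=donors,
        villages=villages,
        gene_ids=gene_ids,
        counts=counts,
        nuclei=nuclei,
        genotypes=genotypes,
        snp_obs=snp_obs,
        outlier_truth=outlier_ids,
        baseline_log_weights=base_log_w,
    )


def simulate_factor_matrix(
    n_donors: int = 180,
    cell_types: Sequence[str] = ("glutamatergic", "gabaergic", "astrocyte"),
    n_genes_per_type: int = 200,
    n_factors: int = 1,
    age_slope: float = -0.02,
    case_shift: float = -0.5,
    score_noise_sd: float = 0.3,
    loading_density: float = 0.3,
    snr: float = 2.0,
    seed: int = 0,
):
    """Donor-level concatenated expression matrix with planted factors.

    Builds the donor x (gene, cell type) matrix the latent factor model
    ingests directly: X = scores @ loadings.T + noise, with Gaussian noise
    scaled so that var(signal) / var(noise) equals ``snr``.  Each planted
    factor loads on a random ``loading_density`` fraction of genes in every
    cell type (distinct gene sets per cell type, mimicking a program that
    uses different genes in different cell types).

    Returns ``(X, donors, truth)`` where X is a donors x features DataFrame
    with features named ``GENE_celltype`` and ``truth`` holds the planted
    scores and loadings.
    """
    rng = np.random.default_rng(seed)
    loadings = {}
    for ct in cell_types:
        L = np.zeros((n_genes_per_type, n_factors))
        for k in range(n_factors):
            n_hit = max(1, int(round(loading_density * n_genes_per_type)))
            hit = rng.choice(n_genes_per_type, size=n_hit, replace=False)
            L[hit, k] = rng.normal(0.0, 1.0, size=n_hit)
        loadings[ct] = L
    spec = ProgramSpec(
        n_factors=n_factors,
        loadings_per_celltype=loadings,
        age_slope=age_slope,
        case_shift=case_shift,
        score_noise_sd=score_noise_sd,
    )
    cfg = VillageConfig(n_donors=n_donors, village_size=min(20, n_donors))
    donors = make_donors(cfg, rng)
    donors = plant_programs(donors, spec, seed=int(rng.integers(0, 2**31 - 1)))

    S = np.vstack([d.program_scores for d in donors])  # donors x K
    Lfull = np.vstack([loadings[ct] for ct in cell_types])  # features x K
    signal = S @ Lfull.T
    sig_var = signal.var()
    noise_sd = np.sqrt(sig_var / snr) if snr > 0 else 0.0
    X = signal + rng.normal(0.0, noise_sd, size=signal.shape)

    features = [
        f"GENE{g:04d}_{ct}" for ct in cell_types for g in range(n_genes_per_type)
    ]
    Xdf = pd.DataFrame(X, index=[d.donor_id for d in donors], columns=features)
    truth = {
        "scores": pd.DataFrame(
            S, index=Xdf.index, columns=[f"factor{k+1}" for k in range(n_factors)]
        ),
        "loadings": pd.DataFrame(
            Lfull, index=features, columns=[f"factor{k+1}" for k in range(n_factors)]
        ),
        "spec": spec,
        "noise_sd": noise_sd,
    }
    return Xdf, donors, truth


def simulate_umi_records(
    families: Sequence[Sequence[str]] = (("C4A", "C4B"), ("SERF1A", "SERF1B", "SERF1C")),
    n_single_genes: int = 20,
    n_cells: int = 50,
    umis_per_cell: int = 100,
    family_weight: float = 0.1,
    unique_read_rate: float = 0.0,
    seed: int = 0,
):
    """Read-level UMI records with planted co-ambiguous paralog families.

    Each UMI originates from either a singleton gene (unique-high-quality
    read) or a paralog family (low-quality reads hitting every family
    member).  ``unique_read_rate`` is the per-family-UMI chance that one
    read nevertheless maps uniquely to the true member, emulating the rare
    uniquely mapping paralog reads.

    Returns ``(records, truth)``: a DataFrame with columns
    (cell_barcode, umi, gene_id, mapq_class) and a dict with the planted
    families plus the per-cell family UMI counts a collapsed single-copy
    reference would report.
    """
    rng = np.random.default_rng(seed)
    families = [tuple(sorted(f)) for f in families]
    single_genes = [f"SG{g:03d}" for g in range(n_single_genes)]
    n_fam = len(families)
    # UMI source distribution: each family gets family_weight, singles share the rest
    probs = np.full(n_fam + n_single_genes, 0.0)
    probs[:n_fam] = family_weight
    probs[n_fam:] = (1.0 - family_weight * n_fam) / n_single_genes
    if np.any(probs < 0):
        raise ValueError("family_weight too large for the number of families")

    rows = []
    oracle = np.zeros((n_fam, n_cells), dtype=np.int64)
    for c in range(n_cells):
        cell = f"CELL{c:04d}"
        for u in range(umis_per_cell):
            umi = f"{cell}:UMI{u:04d}"
            src = int(rng.choice(len(probs), p=probs))
            if src < n_fam:
                fam = families[src]
                oracle[src, c] += 1
                true_member = fam[int(rng.integers(len(fam)))]
                if unique_read_rate > 0 and rng.random() < unique_read_rate:
                    rows.append((cell, umi, true_member, "unique-high-quality"))
                for g in fam:
                    rows.append((cell, umi, g, "multi-low-quality"))
            else:
                gene = single_genes[src - n_fam]
                rows.append((cell, umi, gene, "unique-high-quality"))
    records = pd.DataFrame(
        rows, columns=["cell_barcode", "umi", "gene_id", "mapq_class"]
    )
    oracle_df = pd.DataFrame(
        oracle,
        index=["+".join(f) for f in families],
        columns=[f"CELL{c:04d}" for c in range(n_cells)],
    )
    truth = {"families": families, "single_copy_counts": oracle_df}
    return records, truth


def _write_vcf(genotypes: pd.DataFrame, path: Path) -> None:
    donors = list(genotypes.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(donors) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, snp in enumerate(genotypes.columns):
            gts = "\t".join(gt_map[int(g)] for g in genotypes[snp])
            fh.write(f"1\t{j + 1}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def write_village(sim: VillageSimulation, directory: str | Path,
                  overwrite: bool = False) -> None:
    """Write a simulation to disk in the package's on-disk layout.

    Per village: Matrix Market counts + barcodes.tsv + features.tsv.  Study
    level: genotypes as both long TSV and VCF, SNP observations TSV, donor
    metadata TSV, nucleus table TSV, and a ground-truth JSON.  Round-trips
    losslessly through the readers in :mod:`villagefactor.io`.
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{directory} exists and is not empty; pass overwrite=True"
        )
    directory.mkdir(parents=True, exist_ok=True)

    for v in range(len(sim.villages)):
        vdir = directory / f"village_{v}"
        vdir.mkdir(exist_ok=True)
        mask = (sim.nuclei["village"] == v).to_numpy()
        sub = sim.counts[:, mask].tocoo()
        mmwrite(str(vdir / "matrix.mtx"), sub, field="integer")
        pd.Series(sim.nuclei.loc[mask, "barcode"]).to_csv(
            vdir / "barcodes.tsv", index=False, header=False
        )
        pd.Series(sim.gene_ids).to_csv(
            vdir / "features.tsv", index=False, header=False
        )

    long = sim.genotypes.stack().reset_index()
    long.columns = ["donor_id", "snp_id", "dosage"]
    long = long[["snp_id", "donor_id", "dosage"]]
    long.to_csv(directory / "genotypes.tsv", sep="\t", index=False)
    _write_vcf(sim.genotypes, directory / "genotypes.vcf")

    sim.snp_obs.to_csv(directory / "snp_observations.tsv", sep="\t", index=False)
    meta = pd.DataFrame(
        {
            "donor_id": [d.donor_id for d in sim.donors],
            "age": [d.age for d in sim.donors],
            "sex": [d.sex for d in sim.donors],
            "status": [d.status for d in sim.donors],
        }
    )
    meta.to_csv(directory / "metadata.tsv", sep="\t", index=False)
    sim.nuclei.to_csv(directory / "nuclei.tsv", sep="\t", index=False)

    truth = {
        "villages": sim.villages,
        "outlier_donors": sim.outlier_truth,
        "metagene_families": [list(f) for f in sim.metagene_truth],
        "program_scores": {
            d.donor_id: (d.program_scores.tolist()
                         if d.program_scores is not None else None)
            for d in sim.donors
        },
        "total_umis": int(sim.counts.sum()),
    }
    with open(directory / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
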