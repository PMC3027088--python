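"""Sibship-design study simulator.

Generates rosters, CNV-SNP genotype tables, covariates and a log-scale
quantitative trait with exactly the structure the association model assumes:

* families are full sibships without genotyped parents (the HyperGEN
  ascertainment); the default family-size histogram is the published cohort
  roster (421 families, 1,086 individuals);
* genotypes are inherited Mendelianly from two latent parents per family, so
  sibs share on average half their alleles; a two-founder-population
  admixture model with Balding-Nichols per-marker frequency divergence makes
  principal-component adjustment consequential;
* at a configurable fraction of loci a rare deletion (or duplication) allele
  segregates like a Mendelian allele, producing non-diploid CNV-SNP calls;
* ln(trait) is built additively from intercept, age, age^2, sex, center,
  ancestry, optional causal-marker effects beta1*(a-b) + beta2*(a+b), a
  family random intercept gamma ~ N(0, sigma2_family) and residual
  epsilon ~ N(0, sigma2_resid).

All randomness flows from ``SimConfig.seed`` through independent child
streams, so identical configurations give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import HYPERGEN_FAMILY_HISTOGRAM
from .exceptions import ValidationError
from .io import GenotypeTable, MARKER_COLUMNS

N_AUTOSOMES = 22


@dataclass
class SimConfig:
    """Study-generating parameters; defaults emulate the HyperGEN cohort."""

    family_size_histogram: dict[int, int] = field(
        default_factory=lambda: dict(HYPERGEN_FAMILY_HISTOGRAM)
    )
    n_markers: int = 1000
    maf_range: tuple[float, float] = (0.16, 0.44)
    cnv_locus_fraction: float = 0.05
    cnv_allele_freq: float = 0.005        # rare copy-number allele (< 1%)
    cnv_kind: str = "deletion"            # or "duplication"
    n_causal: int = 0
    beta1: float = 0.05                   # per-allele effect on ln(trait)
    beta2: float = 0.0                    # per-copy effect on ln(trait)
    causal_on_cnv: bool = False
    sigma2_family: float = 0.0053
    sigma2_resid: float = 0.0079
    alpha: float = math.log(3.26)         # baseline ln(trait), trait in cm
    phi_age: float = 0.003
    phi_age2: float = -1e-5
    phi_sex: float = -0.08                # female (sex==2) vs male
    phi_center: float = 0.01              # second center vs first
    phi_ancestry: float = 0.15            # stands in for the PC axes
    divergence: float = 0.1               # Balding-Nichols Fst-like parameter
    ancestry_beta: tuple[float, float] = (1.0, 1.0)
    p_female: float = 0.666
    center_props: dict[str, float] = field(
        default_factory=lambda: {"AL": 856.0, "NC": 230.0}
    )
    age_mean: float = 43.9
    age_sd: float = 13.4
    age_bounds: tuple[float, float] = (18.0, 85.0)
    confidence_beta: tuple[float, float] = (0.5, 30.0)
    missing_rate: float = 0.0
    max_copy: int = 4
    seed: int = 0


@dataclass
class SimTruth:
    """Generative ground truth recorded alongside a simulated study."""

    causal_markers: list[tuple[str, float, float]]
    sigma2_family: float
    sigma2_resid: float
    covariate_effects: dict[str, float]
    ancestry: pd.Series                   # per individual, in [0, 1]
    family_effects: pd.Series             # gamma per family
    cnv_marker_ids: list[str]
    seed: int


@dataclass
class SimStudy:
    genotypes: GenotypeTable
    roster: pd.DataFrame
    pheno: pd.DataFrame
    truth: SimTruth


def build_roster(
    histogram: dict[int, int],
    seed: int = 0,
    p_female: float = 0.666,
    center_props: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Expand a family-size histogram into an individual-level roster.

    Creates exactly ``sum(histogram.values())`` families; a family of size s
    contributes s individuals.  Sex is Bernoulli(p_female) coded 1=male,
    2=female; recruitment center is drawn with the given proportions.
    """
    if not histogram or sum(histogram.values()) == 0:
        raise ValidationError("empty family-size histogram")
    if any(c < 0 for c in histogram.values()):
        raise ValidationError("negative family count in histogram")
    center_props = center_props or {"AL": 856.0, "NC": 230.0}
    labels = list(center_props)
    weights = np.array([center_props[c] for c in labels], dtype=float)
    weights = weights / weights.sum()
    rng = np.random.default_rng([seed, 11])

    fam_ids, ind_ids, sizes = [], [], []
    f = 0
    for size in sorted(histogram):
        for _ in range(histogram[size]):
            f += 1
            fam = f"F{f:04d}"
            for k in range(1, size + 1):
                fam_ids.append(fam)
                ind_ids.append(f"{fam}_{k:02d}")
            sizes.append(size)
    n = len(ind_ids)
    sex = np.where(rng.random(n) < p_female, 2, 1)
    # center is a family-level attribute (families were recruited at a site)
    fam_center = rng.choice(len(labels), size=f, p=weights)
    fam_index = pd.factorize(pd.Series(fam_ids))[0]
    center = [labels[fam_center[i]] for i in fam_index]
    return pd.DataFrame(
        {"family_id": fam_ids, "individual_id": ind_ids, "sex": sex, "center": center}
    )


def _founder_frequencies(rng, config: SimConfig):
    lo, hi = config.maf_range
    p_anc = rng.uniform(lo, hi, config.n_markers)
    f = config.divergence
    if f > 0:
        shape = (1.0 - f) / f
        p1 = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
        p2 = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
    else:
        p1 = p_anc.copy()
        p2 = p_anc.copy()
    return np.clip(p1, 0.01, 0.99), np.clip(p2, 0.01, 0.99)


def _marker_metadata(n_markers: int) -> pd.DataFrame:
    chrom = 1 + (np.arange(n_markers) * N_AUTOSOMES) // max(n_markers, 1)
    chrom = np.minimum(chrom, N_AUTOSOMES)
    pos = np.empty(n_markers, dtype=int)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        pos[idx] = 100_000 + 25_000 * np.arange(len(idx))
    return pd.DataFrame(
        {
            "marker_id": [f"m{i + 1:06d}" for i in range(n_markers)],
            "chrom": chrom.astype(str),
            "pos": pos,
            "allele_a": "A",
            "allele_b": "B",
        }
    )[MARKER_COLUMNS]


def simulate_genotypes(
    roster: pd.DataFrame, config: SimConfig, seed: int | None = None
) -> tuple[GenotypeTable, dict]:
    """Draw CNV-SNP genotypes for a roster under the admixed sibship model.

    Per family, two latent parental diplotypes are drawn from the family's
    ancestry-mixed allele frequencies; each sib inherits one haplotype from
    each parent independently per marker (markers are unlinked).  At CNV loci
    a deletion (or duplication) allele rides on haplotypes with frequency
    ``cnv_allele_freq``; copy number is the number of surviving (or
    amplified) copies and a/b count the SNP alleles on those copies.

    Returns the table plus a dict of partial truth (ancestry per individual,
    CNV marker ids, founder frequencies).
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([seed, 23])
    m = config.n_markers
    fam_codes, fam_labels = pd.factorize(roster["family_id"])
    n_fam = len(fam_labels)
    n = len(roster)

    p1, p2 = _founder_frequencies(rng, config)
    a_b = config.ancestry_beta
    ancestry_fam = rng.beta(a_b[0], a_b[1], n_fam) if config.divergence > 0 else np.full(n_fam, 0.5)
    # per-family B-allele frequency mixes the two founder populations
    q = ancestry_fam[None, :] * p1[:, None] + (1.0 - ancestry_fam[None, :]) * p2[:, None]

    # four parental haplotypes per family: B-allele indicator and CNV allele
    hap_b = (rng.random((m, n_fam, 4)) < q[:, :, None]).astype(np.int8)
    n_cnv = int(round(config.cnv_locus_fraction * m))
    cnv_rows = np.sort(rng.choice(m, size=n_cnv, replace=False)) if n_cnv else np.array([], int)
    hap_cnv = np.zeros((m, n_fam, 4), dtype=np.int8)
    if n_cnv:
        hap_cnv[cnv_rows] = (
            rng.random((n_cnv, n_fam, 4)) < config.cnv_allele_freq
        ).astype(np.int8)
    if config.cnv_kind == "deletion":
        hap_copies = (1 - hap_cnv).astype(np.int8)
    elif config.cnv_kind == "duplication":
        hap_copies = (1 + hap_cnv).astype(np.int8)
    else:
        raise ValidationError(f"unknown cnv_kind {config.cnv_kind!r}")

    # Mendelian transmission: each child picks one maternal and one paternal
    # haplotype independently at every (unlinked) marker
    rows = np.arange(m)[:, None]
    cols = fam_codes[None, :]
    pick_m = rng.integers(0, 2, size=(m, n))
    pick_p = rng.integers(2, 4, size=(m, n))
    b1 = hap_b[rows, cols, pick_m]
    b2 = hap_b[rows, cols, pick_p]
    c1 = hap_copies[rows, cols, pick_m]
    c2 = hap_copies[rows, cols, pick_p]
    total = (c1 + c2).astype(np.int16)
    b_count = (b1 * c1 + b2 * c2).astype(np.int16)
    a_count = total - b_count

    conf = rng.beta(*config.confidence_beta, size=(m, n))
    missing = (
        rng.random((m, n)) < config.missing_rate
        if config.missing_rate > 0
        else np.zeros((m, n), dtype=bool)
    )

    table = GenotypeTable(
        markers=_marker_metadata(m),
        samples=list(roster["individual_id"]),
        a=a_count,
        b=b_count,
        confidence=conf,
        missing=missing,
        max_copy=max(config.max_copy, 2 * int(hap_copies.max())),
    )
    partial = {
        "ancestry": pd.Series(ancestry_fam[fam_codes], index=roster["individual_id"].values),
        "cnv_marker_ids": list(table.markers["marker_id"].iloc[cnv_rows]),
        "founder_freqs": (p1, p2),
    }
    return table, partial


def simulate_phenocov(
    roster: pd.DataFrame,
    genotypes: GenotypeTable,
    truth: SimTruth,
    config: SimConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate the phenotype/covariate table from recorded truth.

    ln(trait) = alpha + sum_c [beta1*(a-b) + beta2*(a+b)] + phi_age*age +
    phi_age2*age^2 + phi_sex*1[female] + phi_center*1[center2] +
    phi_ancestry*pi + gamma_family + eps, trait = exp(.).
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([seed, 37])
    n = len(roster)
    lo, hi = config.age_bounds
    a_std = (lo - config.age_mean) / config.age_sd
    b_std = (hi - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(
        a_std, b_std, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )
    eff = truth.covariate_effects
    female = (roster["sex"].to_numpy() == 2).astype(float)
    centers = sorted(roster["center"].unique())
    center2 = (roster["center"].to_numpy() == centers[-1]).astype(float) if len(centers) > 1 else np.zeros(n)
    ancestry = truth.ancestry.reindex(roster["individual_id"]).to_numpy()

    ln_y = (
        eff["alpha"]
        + eff["phi_age"] * age
        + eff["phi_age2"] * age**2
        + eff["phi_sex"] * female
        + eff["phi_center"] * center2
        + eff["phi_ancestry"] * ancestry
    )
    sample_pos = {s: j for j, s in enumerate(genotypes.samples)}
    order = np.array([sample_pos[i] for i in roster["individual_id"]])
    for marker_id, beta1, beta2 in truth.causal_markers:
        i = genotypes.marker_index(marker_id)
        a = genotypes.a[i, order].astype(float)
        b = genotypes.b[i, order].astype(float)
        ln_y += beta1 * (a - b) + beta2 * (a + b)

    gamma = truth.family_effects.reindex(roster["family_id"]).to_numpy()
    eps = rng.normal(0.0, math.sqrt(truth.sigma2_resid), n) if truth.sigma2_resid > 0 else 0.0
    ln_y = ln_y + gamma + eps
    return pd.DataFrame(
        {
            "individual_id": roster["individual_id"],
            "trait": np.exp(ln_y),
            "age": age,
            "sex": roster["sex"],
            "center": roster["center"],
        }
    )


def simulate_study(config: SimConfig) -> SimStudy:
    """Roster, genotypes, covariates and phenotype in one seeded call."""
    roster = build_roster(
        config.family_size_histogram,
        seed=config.seed,
        p_female=config.p_female,
        center_props=config.center_props,
    )
    genotypes, partial = simulate_genotypes(roster, config)
    rng = np.random.default_rng([config.seed, 53])

    causal: list[tuple[str, float, float]] = []
    if config.n_causal > 0:
        pool = (
            partial["cnv_marker_ids"]
            if config.causal_on_cnv
            else [
                mid
                for mid in genotypes.markers["marker_id"]
                if mid not in set(partial["cnv_marker_ids"])
            ]
        )
        if config.n_causal > len(pool):
            raise ValidationError("n_causal exceeds eligible marker count")
        chosen = rng.choice(len(pool), size=config.n_causal, replace=False)
        causal = [(pool[int(i)], config.beta1, config.beta2) for i in np.sort(chosen)]

    fam_labels = pd.unique(roster["family_id"])
    gamma = (
        rng.normal(0.0, math.sqrt(config.sigma2_family), len(fam_labels))
        if config.sigma2_family > 0
        else np.zeros(len(fam_labels))
    )
    # centre the expected covariate contribution into the intercept so the
    # simulated trait mean sits at exp(alpha) regardless of effect sizes
    weights = np.array(list(config.center_props.values()), dtype=float)
    w2 = weights[-1] / weights.sum() if len(weights) > 1 else 0.0
    a_b = config.ancestry_beta
    mean_anc = a_b[0] / (a_b[0] + a_b[1]) if config.divergence > 0 else 0.5
    alpha_eff = config.alpha - (
        config.phi_age * config.age_mean
        + config.phi_age2 * (config.age_mean**2 + config.age_sd**2)
        + config.phi_sex * config.p_female
        + config.phi_center * w2
        + config.phi_ancestry * mean_anc
    )
    truth = SimTruth(
        causal_markers=causal,
        sigma2_family=config.sigma2_family,
        sigma2_resid=config.sigma2_resid,
        covariate_effects={
            "alpha": alpha_eff,
            "phi_age": config.phi_age,
            "phi_age2": config.phi_age2,
            "phi_sex": config.phi_sex,
            "phi_center": config.phi_center,
            "phi_ancestry": config.phi_ancestry,
        },
        ancestry=partial["ancestry"],
        family_effects=pd.Series(gamma, index=fam_labels),
        cnv_marker_ids=partial["cnv_marker_ids"],
        seed=config.seed,
    )
    pheno = simulate_phenocov(roster, genotypes, truth, config)
    return SimStudy(genotypes=genotypes, roster=roster, pheno=pheno, truth=truth)
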