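"""Two-stage genome-wide joint SNP/CNV association scan.

Stage 1 is the GRAMMAR screen: fit the covariates-plus-family mixed model
once without any genotype, form the conditional residuals
Y* = y - fixed part - family BLUP, and regress Y* on each marker's
(contrast, total) = (a-b, a+b) terms by ordinary least squares.  The screen
is fast and deliberately conservative; its k smallest p-values select the
markers that stage 2 refits with the full mixed model (per-marker REML,
family random intercept, PCs, age, age^2, sex, center) and tests with the
joint Wald chi-square of beta1 = beta2 = 0.  Markers where one genotype axis
is invariant or collinear fall back to the 1-df test of the remaining axis.

Genome-wide significance uses a fixed threshold (default 5e-7, strict
inequality) on the stage-2 p-value.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from . import io as cjio
from .exceptions import FitError, ValidationError
from .io import GenotypeTable, apply_confidence_filter, qc_filter
from .lmm import (
    ALLELE_CONTRAST,
    COPY_TOTAL,
    FamilyLMM,
    conditional_residuals,
    wald_joint_test,
)
from .pca import PcResult, compute_genotype_pcs, select_num_pcs
from .report import RunReport, genomic_inflation_lambda

logger = logging.getLogger(__name__)

GENOMEWIDE_ALPHA = 5e-7
INVARIANT_TOL = 1e-12
COLLINEAR_TOL = 1e-8

RESULT_COLUMNS = [
    "marker_id", "chrom", "pos", "maf", "cnv_rate", "n_used",
    "beta1", "se1", "beta2", "se2",
    "stage1_stat", "stage1_df", "stage1_p",
    "stage2_stat", "stage2_df", "stage2_p",
    "dropped_reason", "significant",
]


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

@dataclass
class NullDesign:
    """Aligned covariate design for the no-genotype mixed model."""

    ids: np.ndarray            # individual ids, row-aligned
    y: np.ndarray              # ln(trait)
    X: np.ndarray              # covariates, no intercept column
    names: list[str]
    groups: np.ndarray         # family ids, row-aligned
    n_dropped: int


def build_null_design(
    pheno: pd.DataFrame,
    roster: pd.DataFrame,
    pcs: PcResult | None = None,
    n_pcs: int = 4,
    trait_pre_transformed: bool = False,
    center_age: bool = False,
) -> NullDesign:
    """Assemble ln(trait) and the fixed covariates: PCs, age, age^2, sex,
    center (dummy-coded, first level reference).

    Age^2 is built internally from age (raw by default; ``center_age``
    centres age before squaring).  Individuals missing any covariate are
    dropped with a logged count; a single-level center column is dropped
    with a warning rather than an error.
    """
    extra = set(pheno["individual_id"]) - set(roster["individual_id"])
    if extra:
        raise ValidationError(
            f"{len(extra)} phenotyped individuals absent from roster, e.g. {sorted(extra)[:3]}"
        )
    df = pheno.merge(roster[["family_id", "individual_id"]], on="individual_id", how="inner")

    y = df["trait"].to_numpy(dtype=float)
    if not trait_pre_transformed:
        y = np.log(y)

    cols: dict[str, np.ndarray] = {}
    if pcs is not None and n_pcs > 0:
        scores = pcs.scores.reindex(df["individual_id"])
        avail = min(n_pcs, scores.shape[1])
        for j in range(avail):
            cols[f"pc{j + 1}"] = scores.iloc[:, j].to_numpy(dtype=float)
    else:
        pheno_pcs = [c for c in pheno.columns if c.startswith("pc")]
        for c in pheno_pcs[:n_pcs]:
            cols[c] = df[c].to_numpy(dtype=float)

    age = df["age"].to_numpy(dtype=float)
    age_c = age - age.mean() if center_age else age
    cols["age"] = age
    cols["age2"] = age_c**2
    cols["sex_female"] = (df["sex"].to_numpy() == 2).astype(float)

    centers = pd.Categorical(df["center"].astype(str))
    if len(centers.categories) > 1:
        for level in centers.categories[1:]:
            cols[f"center_{level}"] = (centers == level).astype(float)
    else:
        logger.warning("single recruitment center; center covariate dropped")

    X = np.column_stack(list(cols.values())) if cols else np.empty((len(df), 0))
    names = list(cols)
    keep_rows = np.isfinite(y) & np.isfinite(X).all(axis=1)
    n_dropped = int((~keep_rows).sum())
    if n_dropped:
        logger.info("null design: %d individuals dropped for missing covariates", n_dropped)
    df, y, X = df.loc[keep_rows], y[keep_rows], X[keep_rows]

    # drop constant covariate columns (aliased with the intercept)
    keep_cols = X.std(axis=0) > INVARIANT_TOL if X.size else np.array([], bool)
    for name, ok in zip(list(names), keep_cols):
        if not ok:
            logger.warning("covariate %r is constant; dropped", name)
    X = X[:, keep_cols]
    names = [nm for nm, ok in zip(names, keep_cols) if ok]
    return NullDesign(
        ids=df["individual_id"].to_numpy(),
        y=y,
        X=X,
        names=names,
        groups=df["family_id"].to_numpy(),
        n_dropped=n_dropped,
    )


def fit_null_model(
    pheno: pd.DataFrame,
    roster: pd.DataFrame,
    pcs: PcResult | None = None,
    n_pcs: int = 4,
    trait_pre_transformed: bool = False,
    min_n: int = 50,
    center_age: bool = False,
) -> tuple[FamilyLMM, NullDesign]:
    """Fit the no-genotype mixed model whose conditional residuals feed the
    GRAMMAR screen."""
    design = build_null_design(
        pheno, roster, pcs=pcs, n_pcs=n_pcs,
        trait_pre_transformed=trait_pre_transformed, center_age=center_age,
    )
    if len(design.y) < min_n:
        raise FitError(f"only {len(design.y)} complete individuals (< {min_n})")
    fit = FamilyLMM(fit_intercept=True).fit(
        design.X, design.y, groups=design.groups, feature_names=design.names
    )
    return fit, design


# ---------------------------------------------------------------------------
# genotype term preparation
# ---------------------------------------------------------------------------

def _genotype_terms(contrast: np.ndarray, total: np.ndarray):
    """Apply the invariant/collinear dropping rules; returns (columns, labels,
    reason) where reason is set when anything was dropped."""
    terms, labels = [], []
    reason = None
    if np.var(contrast) > INVARIANT_TOL:
        terms.append(contrast)
        labels.append(ALLELE_CONTRAST)
    else:
        reason = "invariant"
    if np.var(total) > INVARIANT_TOL:
        terms.append(total)
        labels.append(COPY_TOTAL)
    else:
        reason = "invariant"
    if len(terms) == 2:
        centered = np.column_stack([t - t.mean() for t in terms])
        sv = np.linalg.svd(centered, compute_uv=False)
        if sv[-1] < COLLINEAR_TOL * sv[0]:
            terms, labels = terms[:1], labels[:1]
            reason = "collinear"
    return terms, labels, reason


# ---------------------------------------------------------------------------
# stage 1: GRAMMAR screen
# ---------------------------------------------------------------------------

def stage1_grammar_scan(genotypes: GenotypeTable, residuals: pd.Series) -> pd.DataFrame:
    """OLS of the conditional residuals Y* on each marker's genotype terms.

    ``residuals`` is indexed by individual id (the output of the null fit).
    Returns one row per marker with the stage-1 joint statistic, df and
    p-value; markers with no retainable genotype term get p = 1 and a
    ``dropped_reason``.
    """
    resid_index = pd.Index(residuals.index)
    col_idx = np.array(
        [j for j, s in enumerate(genotypes.samples) if s in set(resid_index)]
    )
    if col_idx.size == 0:
        raise ValidationError("no overlap between genotyped and phenotyped individuals")
    sample_ids = [genotypes.samples[j] for j in col_idx]
    r_all = residuals.reindex(sample_ids).to_numpy(dtype=float)

    a = genotypes.a[:, col_idx].astype(float)
    b = genotypes.b[:, col_idx].astype(float)
    miss = genotypes.missing[:, col_idx]

    rows = []
    meta = genotypes.markers
    for i in range(genotypes.n_markers):
        usable = ~miss[i]
        n_u = int(usable.sum())
        base = {
            "marker_id": meta["marker_id"].iloc[i],
            "chrom": str(meta["chrom"].iloc[i]),
            "pos": int(meta["pos"].iloc[i]),
            "n_used": n_u,
        }
        if n_u == 0:
            rows.append({**base, "maf": np.nan, "cnv_rate": np.nan,
                         "stage1_stat": 0.0, "stage1_df": 0, "stage1_p": 1.0,
                         "dropped_reason": "invariant"})
            continue
        contrast = (a[i] - b[i])[usable]
        total = (a[i] + b[i])[usable]
        copies = total.sum()
        maf = float(min((total + contrast).sum(), (total - contrast).sum()) / (2 * copies)) if copies else 0.0
        cnv_rate = float(np.mean(total != 2))
        terms, labels, reason = _genotype_terms(contrast, total)
        if not terms or n_u <= len(terms) + 2:
            rows.append({**base, "maf": maf, "cnv_rate": cnv_rate,
                         "stage1_stat": 0.0, "stage1_df": 0, "stage1_p": 1.0,
                         "dropped_reason": reason or "invariant"})
            continue
        X = np.column_stack([np.ones(n_u)] + terms)
        r = r_all[usable]
        xtx = X.T @ X
        xty = X.T @ r
        coef = np.linalg.solve(xtx, xty)
        rss = float(r @ r - coef @ xty)
        dof = n_u - X.shape[1]
        sigma2 = max(rss, 0.0) / dof
        cov = sigma2 * np.linalg.inv(xtx)
        g = np.arange(1, X.shape[1])
        beta_g = coef[g]
        stat = float(beta_g @ np.linalg.solve(cov[np.ix_(g, g)], beta_g)) if sigma2 > 0 else np.inf
        df_t = len(g)
        p = float(stats.chi2.sf(stat, df_t))
        rows.append({**base, "maf": maf, "cnv_rate": cnv_rate,
                     "stage1_stat": stat, "stage1_df": df_t, "stage1_p": p,
                     "dropped_reason": reason})
    out = pd.DataFrame(rows)
    for c in ("beta1", "se1", "beta2", "se2", "stage2_stat", "stage2_p"):
        out[c] = np.nan
    out["stage2_df"] = pd.array([pd.NA] * len(out), dtype="Int64")
    out["significant"] = False
    return out[RESULT_COLUMNS]


# ---------------------------------------------------------------------------
# screening and stage 2
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    """Markers admitted to stage 2, ranked by ascending stage-1 p-value."""

    marker_ids: list[str]
    k: int
    p_cutoff_attained: float


def _chrom_rank(chrom: pd.Series) -> pd.Series:
    num = pd.to_numeric(chrom, errors="coerce")
    return num.fillna(10_000)


def select_top_k(results: pd.DataFrame, k: int = 1000) -> ScreenResult:
    """The k markers with smallest stage-1 p; ties broken by genomic order
    (chromosome, position, marker_id)."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    df = results.copy()
    df["_cr"] = _chrom_rank(df["chrom"])
    df = df.sort_values(["stage1_p", "_cr", "pos", "marker_id"], kind="mergesort")
    if len(df) < k:
        logger.warning("only %d markers available for top-%d screen", len(df), k)
    top = df.head(k)
    return ScreenResult(
        marker_ids=list(top["marker_id"]),
        k=k,
        p_cutoff_attained=float(top["stage1_p"].max()) if len(top) else float("nan"),
    )


def stage2_full_scan(
    genotypes: GenotypeTable,
    pheno: pd.DataFrame,
    roster: pd.DataFrame,
    pcs: PcResult | None = None,
    screen: ScreenResult | None = None,
    n_pcs: int = 4,
    trait_pre_transformed: bool = False,
    center_age: bool = False,
) -> pd.DataFrame:
    """Full mixed-model refit of the screened markers.

    Per marker the family random-intercept model with all covariates plus
    the retained genotype terms is REML-refitted (variance components are
    re-estimated each time) and the joint Wald test computed.  Markers whose
    fit fails are reported with a missing stage-2 p and a log entry.
    """
    design = build_null_design(
        pheno, roster, pcs=pcs, n_pcs=n_pcs,
        trait_pre_transformed=trait_pre_transformed, center_age=center_age,
    )
    sample_pos = {s: j for j, s in enumerate(genotypes.samples)}
    try:
        col_idx = np.array([sample_pos[i] for i in design.ids])
    except KeyError as exc:
        raise ValidationError(f"individual {exc} has covariates but no genotypes") from None

    marker_ids = screen.marker_ids if screen is not None else list(genotypes.markers["marker_id"])
    a = genotypes.a[:, col_idx].astype(float)
    b = genotypes.b[:, col_idx].astype(float)
    miss = genotypes.missing[:, col_idx]
    meta = genotypes.markers.set_index("marker_id")

    rows = []
    for marker_id in marker_ids:
        i = genotypes.marker_index(marker_id)
        usable = ~miss[i]
        n_u = int(usable.sum())
        base = {
            "marker_id": marker_id,
            "chrom": str(meta.loc[marker_id, "chrom"]),
            "pos": int(meta.loc[marker_id, "pos"]),
            "n_used": n_u,
        }
        if n_u == 0:
            rows.append({**base, "stage2_p": np.nan, "stage2_df": 0,
                         "dropped_reason": "invariant"})
            continue
        contrast = (a[i] - b[i])[usable]
        total = (a[i] + b[i])[usable]
        terms, labels, reason = _genotype_terms(contrast, total)
        if not terms:
            rows.append({**base, "stage2_p": np.nan, "stage2_df": 0,
                         "dropped_reason": reason})
            continue
        X = np.column_stack([design.X[usable]] + terms)
        names = design.names + labels
        try:
            fit = FamilyLMM(fit_intercept=True).fit(
                X, design.y[usable], groups=design.groups[usable], feature_names=names
            )
            test = wald_joint_test(fit, (ALLELE_CONTRAST, COPY_TOTAL))
        except (FitError, np.linalg.LinAlgError) as exc:
            logger.warning("stage 2 fit failed for %s: %s", marker_id, exc)
            rows.append({**base, "stage2_p": np.nan, "stage2_df": pd.NA,
                         "dropped_reason": "nonconverged"})
            continue
        row = {**base, "stage2_stat": test.statistic, "stage2_df": test.df,
               "stage2_p": test.p_value,
               "dropped_reason": reason or test.dropped_reason}
        for label, b_name, s_name in (
            (ALLELE_CONTRAST, "beta1", "se1"), (COPY_TOTAL, "beta2", "se2"),
        ):
            if label in fit.fixed_names_:
                j = fit.fixed_names_.index(label)
                row[b_name] = float(fit.beta_[j])
                row[s_name] = float(np.sqrt(fit.cov_beta_[j, j]))
        rows.append(row)
    out = pd.DataFrame(rows)
    for c in RESULT_COLUMNS:
        if c not in out.columns:
            out[c] = np.nan
    out["stage2_df"] = out["stage2_df"].astype("Int64")
    out["significant"] = False
    return out[RESULT_COLUMNS]


def flag_significance(results: pd.DataFrame, genomewide_alpha: float = GENOMEWIDE_ALPHA) -> pd.DataFrame:
    """Flag rows with stage-2 p strictly below the genome-wide threshold."""
    if not (0 < genomewide_alpha < 1):
        raise ValidationError("genomewide_alpha outside (0, 1)")
    out = results.copy()
    p2 = pd.to_numeric(out["stage2_p"], errors="coerce")
    out["significant"] = (p2 < genomewide_alpha).fillna(False).astype(bool)
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

class TwoStageScan(BaseEstimator):
    """End-to-end two-stage joint SNP/CNV association scan.

    ``fit(genotypes, roster, pheno)`` runs: confidence filter -> marker QC ->
    genotype PCA -> null mixed-model fit -> GRAMMAR residual screen ->
    top-k selection -> per-marker full mixed-model refit -> significance
    flags.  Results land in ``results_`` (one row per marker; stage-2 fields
    populated for screened markers) and a :class:`RunReport` in ``report_``.
    """

    def __init__(
        self,
        confidence_threshold: float = 0.1,
        min_call_rate: float = 0.95,
        min_maf: float = 0.01,
        n_pcs: int = 4,
        pca_components: int = 10,
        pc_rule: str = "fixed_k",
        k: int = 1000,
        genomewide_alpha: float = GENOMEWIDE_ALPHA,
        trait_pre_transformed: bool = False,
        center_age: bool = False,
        seed: int | None = None,
    ):
        self.confidence_threshold = confidence_threshold
        self.min_call_rate = min_call_rate
        self.min_maf = min_maf
        self.n_pcs = n_pcs
        self.pca_components = pca_components
        self.pc_rule = pc_rule
        self.k = k
        self.genomewide_alpha = genomewide_alpha
        self.trait_pre_transformed = trait_pre_transformed
        self.center_age = center_age
        self.seed = seed

    def fit(self, genotypes: GenotypeTable, roster: pd.DataFrame, pheno: pd.DataFrame):
        report = RunReport(config=self.get_params(), seed=self.seed)
        t0 = time.perf_counter()
        report.count("input", individuals=len(roster),
                     families=roster["family_id"].nunique(),
                     markers=genotypes.n_markers)

        table = apply_confidence_filter(genotypes, self.confidence_threshold)
        table = qc_filter(table, self.min_call_rate, self.min_maf)
        report.count("post_qc", markers=table.n_markers)
        report.log(f"qc done in {time.perf_counter() - t0:.1f}s")

        pcs = None
        n_pcs_used = 0
        if self.n_pcs > 0:
            n_comp = min(self.pca_components, table.n_samples - 1, table.n_markers)
            n_comp = max(n_comp, self.n_pcs)
            pcs = compute_genotype_pcs(table, n_components=n_comp, min_maf=self.min_maf)
            n_pcs_used = select_num_pcs(pcs.eigenvalues, rule=self.pc_rule, k=self.n_pcs)
            report.log(f"pca: {len(pcs.markers_used)} markers, {n_pcs_used} PCs retained")
        self.pcs_ = pcs

        null_fit, design = fit_null_model(
            pheno, roster, pcs=pcs, n_pcs=n_pcs_used,
            trait_pre_transformed=self.trait_pre_transformed,
            center_age=self.center_age,
        )
        self.null_fit_ = null_fit
        report.count("null_model", individuals=null_fit.n_used_,
                     families=int(null_fit.family_effects_.size))
        report.log(
            f"null fit: sigma2_family={null_fit.sigma2_family_:.3g} "
            f"sigma2_resid={null_fit.sigma2_resid_:.3g}"
        )
        residuals = pd.Series(null_fit.conditional_residuals_, index=design.ids)

        stage1 = stage1_grammar_scan(table, residuals)
        tested1 = stage1.loc[stage1["stage1_df"] > 0, "stage1_p"]
        if len(tested1) >= 2:
            report.lambda_stage1 = genomic_inflation_lambda(tested1)
        report.log(f"stage 1 scan of {len(stage1)} markers done "
                   f"({time.perf_counter() - t0:.1f}s)")

        screen = select_top_k(stage1, k=self.k)
        self.screen_ = screen
        report.stage1_cutoff = screen.p_cutoff_attained

        stage2 = stage2_full_scan(
            table, pheno, roster, pcs=pcs, screen=screen, n_pcs=n_pcs_used,
            trait_pre_transformed=self.trait_pre_transformed,
            center_age=self.center_age,
        )
        tested2 = stage2["stage2_p"].dropna()
        if len(tested2) >= 2:
            report.lambda_stage2 = genomic_inflation_lambda(tested2)
        report.count("stage2", markers=len(stage2))
        report.log(f"stage 2 refit done ({time.perf_counter() - t0:.1f}s)")

        results = stage1.set_index("marker_id")
        s2 = stage2.set_index("marker_id")
        cols = ["beta1", "se1", "beta2", "se2", "stage2_stat", "stage2_df", "stage2_p"]
        results.loc[s2.index, cols] = s2[cols]
        results = results.reset_index()[RESULT_COLUMNS]
        results = flag_significance(results, self.genomewide_alpha)
        self.results_ = results
        self.report_ = report
        return self


@dataclass
class PipelineConfig:
    """File-based pipeline configuration (the CLI's ``run`` contract)."""

    genotypes: str
    roster: str
    pheno: str
    confidence_threshold: float = 0.1
    min_call_rate: float = 0.95
    min_maf: float = 0.01
    n_pcs: int = 4
    k: int = 1000
    genomewide_alpha: float = GENOMEWIDE_ALPHA
    trait_pre_transformed: bool = False
    seed: int | None = None
    extra: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> tuple[pd.DataFrame, RunReport]:
    """Load the three input tables, run :class:`TwoStageScan`, return
    (results, report)."""
    genotypes = cjio.read_genotype_table(config.genotypes)
    roster = cjio.read_roster(config.roster)
    pheno = cjio.read_phenocov(config.pheno)
    scan = TwoStageScan(
        confidence_threshold=config.confidence_threshold,
        min_call_rate=config.min_call_rate,
        min_maf=config.min_maf,
        n_pcs=config.n_pcs,
        k=config.k,
        genomewide_alpha=config.genomewide_alpha,
        trait_pre_transformed=config.trait_pre_transformed,
        seed=config.seed,
    ).fit(genotypes, roster, pheno)
    return scan.results_, scan.report_
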