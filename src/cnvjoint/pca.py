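"""Population-stratification principal components from genotype dosages.

Computes the standard centred/scaled-dosage eigendecomposition used to
adjust association models for admixture: per retained marker the dosage is
the B-allele count, mean-imputed where missing, centred, and scaled by
sqrt(p(1-p)) with p the mean dosage / 2; the eigenvectors of the resulting
individual x individual covariance are the PC scores entered as fixed-effect
covariates.

CNV-heavy loci (total copy number != 2 in more than ``max_cnv_rate`` of
samples) are excluded -- dosage scaling assumes diploidy and the PCs are
stratification controls, not CNV summaries.  Residual non-diploid calls at
retained loci are treated as missing and mean-imputed.  Each PC's sign is
fixed so that its marker-loading sum is non-negative, for reproducibility.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import FitError, ValidationError
from .io import GenotypeTable

logger = logging.getLogger(__name__)


@dataclass
class PcResult:
    """PC scores (individuals x K), nonincreasing eigenvalues, markers used."""

    scores: pd.DataFrame
    eigenvalues: np.ndarray
    markers_used: list[str]


class GenotypePCA(BaseEstimator, TransformerMixin):
    """Genotype principal components as a scikit-learn style transformer.

    Parameters
    ----------
    n_components : int, default 10
    min_maf : float, default 0.01
        Dosage-based minor-allele-frequency floor for marker inclusion.
    max_cnv_rate : float, default 0.01
        Markers with a larger fraction of non-diploid calls are excluded.
    thin_every : int or None
        Optional thin-by-count: keep every ``thin_every``-th eligible marker
        (no map-based LD pruning is applied).
    """

    def __init__(self, n_components: int = 10, min_maf: float = 0.01,
                 max_cnv_rate: float = 0.01, thin_every: int | None = None):
        self.n_components = n_components
        self.min_maf = min_maf
        self.max_cnv_rate = max_cnv_rate
        self.thin_every = thin_every

    def _dosage_matrix(self, table: GenotypeTable):
        usable = ~table.missing
        total = np.where(usable, table.a + table.b, 0)
        n_usable = usable.sum(axis=1)
        if (n_usable == 0).any():
            pass  # all-missing markers are simply ineligible below
        diploid = usable & (total == 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            cnv_rate = np.where(
                n_usable > 0, (usable & (total != 2)).sum(axis=1) / np.maximum(n_usable, 1), 1.0
            )
        dosage = np.where(diploid, table.b, np.nan).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.nanmean(dosage, axis=1) / 2.0
        maf = np.minimum(p, 1.0 - p)
        eligible = (
            (cnv_rate <= self.max_cnv_rate)
            & np.isfinite(p)
            & (maf >= self.min_maf)
            & (p > 0)
            & (p < 1)
        )
        idx = np.flatnonzero(eligible)
        if self.thin_every and self.thin_every > 1:
            idx = idx[:: self.thin_every]
        return dosage[idx], p[idx], idx

    def fit(self, table: GenotypeTable, y=None):
        dosage, p, idx = self._dosage_matrix(table)
        k = self.n_components
        if len(idx) < k:
            raise FitError(
                f"only {len(idx)} usable markers for {k} components"
            )
        if table.n_samples < k + 1:
            raise FitError("fewer individuals than components + 1")
        # mean-impute missing, centre, scale by sqrt(p(1-p))
        col_mean = 2.0 * p
        X = np.where(np.isnan(dosage), col_mean[:, None], dosage)
        X = (X - col_mean[:, None]) / np.sqrt(p * (1.0 - p))[:, None]
        X = X.T  # individuals x markers
        G = X @ X.T / X.shape[1]
        evals, evecs = np.linalg.eigh(G)
        order = np.argsort(evals)[::-1][:k]
        evals = np.maximum(evals[order], 0.0)
        evecs = evecs[:, order]
        # sign convention: marker-loading sum non-negative
        loadings = X.T @ evecs
        signs = np.where(loadings.sum(axis=0) < 0, -1.0, 1.0)
        evecs = evecs * signs
        scores = evecs * np.sqrt(evals)

        self.eigenvalues_ = evals
        self.scores_ = pd.DataFrame(
            scores,
            index=pd.Index(table.samples, name="individual_id"),
            columns=[f"pc{j + 1}" for j in range(k)],
        )
        self.markers_used_ = list(table.markers["marker_id"].iloc[idx])
        return self

    def transform(self, table: GenotypeTable = None):
        """Return fitted scores (out-of-sample projection is out of scope)."""
        return self.scores_

    def to_result(self) -> PcResult:
        return PcResult(
            scores=self.scores_,
            eigenvalues=self.eigenvalues_,
            markers_used=self.markers_used_,
        )


def compute_genotype_pcs(
    table: GenotypeTable, n_components: int = 10, min_maf: float = 0.01, **kw
) -> PcResult:
    """Functional wrapper over :class:`GenotypePCA`."""
    return GenotypePCA(n_components=n_components, min_maf=min_maf, **kw).fit(table).to_result()


def select_num_pcs(eigenvalues, rule: str = "fixed_k", k: int = 4) -> int:
    """Choose the number of PCs to carry as covariates.

    ``fixed_k`` returns ``k`` (the conventional four for admixed-cohort
    stratification control); ``eigenvalue_gap`` returns the index before the
    largest successive eigenvalue ratio drop.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if rule == "fixed_k":
        if len(ev) < k:
            raise ValidationError(f"only {len(ev)} eigenvalues for fixed_k={k}")
        return k
    if rule == "eigenvalue_gap":
        if len(ev) < 2 or not np.all(ev > 0) or np.allclose(ev, ev[0]):
            logger.warning("no eigenvalue structure; selecting 1 PC")
            return 1
        ratios = ev[:-1] / ev[1:]
        return int(np.argmax(ratios)) + 1
    raise ValidationError(f"unknown rule {rule!r}")
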