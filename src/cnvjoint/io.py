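"""Domain types, file readers/writers, call filtering and the joint design encoding.

The central object is the :class:`GenotypeTable`: a markers x samples grid of
CNV-SNP calls.  A call at a locus with generic alleles A and B is the pair of
allele counts ``(a, b)`` over however many genomic copies the sample carries
there, plus a call-confidence score in [0, 1] where *lower* means more
certain (the convention of HMM-based CNV-aware genotype callers such as the
Birdsuite/Larry Bird family).  ``a + b`` is the total copy number: 2 for an
ordinary diploid genotype, 0 or 1 under deletion, 3+ under duplication.

Association models downstream use the linear reparameterisation

    contrast = a - b      (additive SNP-allele axis)
    total    = a + b      (additive copy-number axis)

so the per-marker design is produced here, once, by :func:`encode_joint_design`.

On-disk formats (all tab-separated, UTF-8, header row, reals printed to six
significant digits):

* genotype table: ``marker_id  chrom  pos  allele_a  allele_b  <sample>...``
  with cells ``a,b,conf`` or the missing sentinel ``.``
* roster:         ``family_id  individual_id  sex  center``
* phenotype:      ``individual_id  trait  age  sex  center  [pc1 ... pcK]``
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

MISSING_SENTINEL = "."
_REAL_FMT = "%.6g"

MARKER_COLUMNS = ["marker_id", "chrom", "pos", "allele_a", "allele_b"]
ROSTER_COLUMNS = ["family_id", "individual_id", "sex", "center"]
PHENO_COLUMNS = ["individual_id", "trait", "age", "sex", "center"]


@dataclass(frozen=True)
class CnvSnpCall:
    """A single CNV-SNP genotype call: counts of each allele plus confidence.

    ``a`` and ``b`` count the A and B alleles over all copies present, so
    ``a + b`` is the copy number (0 = homozygous deletion).  ``confidence``
    is in [0, 1], lower = more certain.  A missing call carries no usable
    counts and is excluded from every statistic.
    """

    a: int
    b: int
    confidence: float
    missing: bool = False

    def __post_init__(self) -> None:
        if not self.missing:
            if self.a < 0 or self.b < 0:
                raise ValidationError(f"negative allele count in call ({self.a},{self.b})")
            if not (0.0 <= self.confidence <= 1.0):
                raise ValidationError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def total_copy(self) -> int:
        return self.a + self.b


@dataclass
class GenotypeTable:
    """Markers x samples grid of CNV-SNP calls with marker metadata.

    ``markers`` is a DataFrame with columns marker_id, chrom, pos, allele_a,
    allele_b (1-based positions, chromosome as string, autosomes in scope).
    The call grid is stored as dense arrays of shape (n_markers, n_samples).
    """

    markers: pd.DataFrame
    samples: list[str]
    a: np.ndarray
    b: np.ndarray
    confidence: np.ndarray
    missing: np.ndarray
    max_copy: int = 4

    def __post_init__(self) -> None:
        self.markers = self.markers.reset_index(drop=True)
        shape = (len(self.markers), len(self.samples))
        for name in ("a", "b", "confidence", "missing"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ValidationError(
                    f"grid '{name}' has shape {arr.shape}, expected {shape}"
                )
            setattr(self, name, arr)
        self.a = self.a.astype(np.int16)
        self.b = self.b.astype(np.int16)
        self.confidence = self.confidence.astype(float)
        self.missing = self.missing.astype(bool)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.markers["marker_id"].duplicated().any():
            dup = self.markers.loc[self.markers["marker_id"].duplicated(), "marker_id"]
            raise FormatError(f"duplicate marker_id: {dup.iloc[0]!r}")
        if len(set(self.samples)) != len(self.samples):
            raise FormatError("duplicate sample identifiers")
        if (self.markers["pos"] < 1).any():
            raise ValidationError("positions must be 1-based (>= 1)")
        ok = ~self.missing
        if ok.any():
            if (self.a[ok] < 0).any() or (self.b[ok] < 0).any():
                raise ValidationError("negative allele count")
            total = self.a[ok] + self.b[ok]
            if (total > self.max_copy).any():
                raise ValidationError(
                    f"total copy number exceeds max_copy={self.max_copy}"
                )

    # -- conveniences -------------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def call(self, marker_index: int, sample_index: int) -> CnvSnpCall:
        if self.missing[marker_index, sample_index]:
            return CnvSnpCall(0, 0, 1.0, missing=True)
        return CnvSnpCall(
            int(self.a[marker_index, sample_index]),
            int(self.b[marker_index, sample_index]),
            float(self.confidence[marker_index, sample_index]),
        )

    def subset_markers(self, index) -> "GenotypeTable":
        index = np.asarray(index)
        return replace(
            self,
            markers=self.markers.iloc[index].reset_index(drop=True),
            a=self.a[index],
            b=self.b[index],
            confidence=self.confidence[index],
            missing=self.missing[index],
        )

    def marker_index(self, marker_id: str) -> int:
        hits = np.flatnonzero((self.markers["marker_id"] == marker_id).to_numpy())
        if hits.size == 0:
            raise KeyError(marker_id)
        return int(hits[0])

    def equals(self, other: "GenotypeTable") -> bool:
        """Semantic equality: missing cells match regardless of stored counts."""
        if self.samples != other.samples:
            return False
        if not self.markers[MARKER_COLUMNS].equals(other.markers[MARKER_COLUMNS]):
            return False
        if not np.array_equal(self.missing, other.missing):
            return False
        ok = ~self.missing
        return (
            np.array_equal(self.a[ok], other.a[ok])
            and np.array_equal(self.b[ok], other.b[ok])
            and np.allclose(self.confidence[ok], other.confidence[ok], rtol=1e-5, atol=1e-9)
        )


@dataclass
class JointDesign:
    """Per-marker regressors of the joint allelic/copy-number model.

    ``contrast[i] = a_i - b_i`` and ``total[i] = a_i + b_i`` are defined only
    where ``usable_mask`` is True (call present and confidence-passing);
    elsewhere they are NaN.  ``|contrast| <= total`` holds elementwise.
    """

    marker_id: str
    contrast: np.ndarray
    total: np.ndarray
    usable_mask: np.ndarray

    @property
    def n_usable(self) -> int:
        return int(self.usable_mask.sum())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_cell(cell: str, max_copy: int, permissive: bool, where: str):
    cell = cell.strip()
    if cell == MISSING_SENTINEL:
        return 0, 0, np.nan, True
    parts = cell.split(",")
    try:
        if len(parts) != 3:
            raise ValueError("expected 'a,b,conf'")
        a, b = int(parts[0]), int(parts[1])
        conf = float(parts[2])
        if a < 0 or b < 0:
            raise ValueError("negative allele count")
        if a + b > max_copy:
            raise ValueError(f"copy number {a + b} > max_copy {max_copy}")
        if not (0.0 <= conf <= 1.0):
            raise ValueError(f"confidence {conf} outside [0, 1]")
    except ValueError as exc:
        if permissive:
            logger.warning("malformed cell %r at %s treated as missing (%s)", cell, where, exc)
            return 0, 0, np.nan, True
        raise FormatError(f"malformed genotype cell {cell!r} at {where}: {exc}") from None
    return a, b, conf, False


def read_genotype_table(path, permissive: bool = False, max_copy: int = 4) -> GenotypeTable:
    """Read the tab-separated genotype table format.

    Each data row is marker metadata followed by one ``a,b,conf`` triplet (or
    ``.``) per sample.  With ``permissive=True`` malformed triplets become
    missing calls instead of raising :class:`FormatError`.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file")
        cols = header.split("\t")
        if cols[: len(MARKER_COLUMNS)] != MARKER_COLUMNS:
            raise FormatError(
                f"{path}: header must start with {MARKER_COLUMNS}, got {cols[:5]}"
            )
        samples = cols[len(MARKER_COLUMNS):]
        n = len(samples)
        meta_rows, grids = [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(MARKER_COLUMNS) + n:
                raise FormatError(
                    f"{path}:{lineno}: ragged row ({len(fields)} fields, "
                    f"expected {len(MARKER_COLUMNS) + n})"
                )
            marker_id, chrom, pos, aa, ab = fields[:5]
            try:
                pos_i = int(pos)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad position {pos!r}") from None
            meta_rows.append((marker_id, chrom, pos_i, aa, ab))
            grids.append(
                [
                    _parse_cell(c, max_copy, permissive, f"{path}:{lineno}")
                    for c in fields[5:]
                ]
            )
    markers = pd.DataFrame(meta_rows, columns=MARKER_COLUMNS)
    if grids:
        arr = np.array(grids, dtype=object)
        a = arr[:, :, 0].astype(np.int16)
        b = arr[:, :, 1].astype(np.int16)
        conf = arr[:, :, 2].astype(float)
        miss = arr[:, :, 3].astype(bool)
    else:
        a = b = np.zeros((0, n), dtype=np.int16)
        conf = np.zeros((0, n))
        miss = np.zeros((0, n), dtype=bool)
    return GenotypeTable(markers, samples, a, b, conf, miss, max_copy=max_copy)


def write_genotype_table(table: GenotypeTable, path) -> None:
    """Write a genotype table; ``read(write(t))`` reproduces ``t`` exactly."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(MARKER_COLUMNS + list(table.samples)) + "\n")
        for i in range(table.n_markers):
            meta = table.markers.iloc[i]
            cells = []
            for j in range(table.n_samples):
                if table.missing[i, j]:
                    cells.append(MISSING_SENTINEL)
                else:
                    conf = _REAL_FMT % table.confidence[i, j]
                    cells.append(f"{table.a[i, j]},{table.b[i, j]},{conf}")
            row = [
                str(meta["marker_id"]),
                str(meta["chrom"]),
                str(int(meta["pos"])),
                str(meta["allele_a"]),
                str(meta["allele_b"]),
            ] + cells
            fh.write("\t".join(row) + "\n")


def read_roster(path) -> pd.DataFrame:
    """Read the family roster (FAM-like: family, individual, sex, center)."""
    df = pd.read_csv(path, sep="\t", dtype={"family_id": str, "individual_id": str,
                                            "center": str})
    missing = set(ROSTER_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: roster missing columns {sorted(missing)}")
    if df["individual_id"].duplicated().any():
        dup = df.loc[df["individual_id"].duplicated(), "individual_id"].iloc[0]
        raise FormatError(f"{path}: duplicate individual {dup!r}")
    if not df["sex"].isin([1, 2]).all():
        raise ValidationError(f"{path}: sex must be coded 1/2")
    return df[ROSTER_COLUMNS].copy()


def write_roster(roster: pd.DataFrame, path) -> None:
    roster[ROSTER_COLUMNS].to_csv(path, sep="\t", index=False)


def read_phenocov(path) -> pd.DataFrame:
    """Read the phenotype/covariate table; trait must be positive (it is
    log-transformed downstream) and age non-negative."""
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str, "center": str})
    missing = set(PHENO_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: phenotype table missing columns {sorted(missing)}")
    if df["individual_id"].duplicated().any():
        dup = df.loc[df["individual_id"].duplicated(), "individual_id"].iloc[0]
        raise FormatError(f"{path}: duplicate individual {dup!r}")
    if (df["trait"] <= 0).any():
        bad = df.loc[df["trait"] <= 0, "individual_id"].iloc[0]
        raise ValidationError(
            f"{path}: non-positive trait for {bad!r} (log transform undefined)"
        )
    if (df["age"] < 0).any():
        raise ValidationError(f"{path}: negative age")
    pc_cols = [c for c in df.columns if c.startswith("pc")]
    return df[PHENO_COLUMNS + pc_cols].copy()


def write_phenocov(pheno: pd.DataFrame, path) -> None:
    out = pheno.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda v: _REAL_FMT % v)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# filtering and encoding
# ---------------------------------------------------------------------------

def apply_confidence_filter(table: GenotypeTable, threshold: float = 0.1) -> GenotypeTable:
    """Set calls with confidence >= ``threshold`` to missing (strict: only
    calls *less than* the threshold are retained).

    Idempotent and monotone: a lower threshold never retains a call a higher
    threshold dropped.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValidationError(f"confidence threshold {threshold} outside (0, 1]")
    with np.errstate(invalid="ignore"):
        drop = (~table.missing) & (table.confidence >= threshold)
    n_drop = int(drop.sum())
    if n_drop:
        logger.info("confidence filter (< %g): %d calls set missing", threshold, n_drop)
    return replace(table, missing=table.missing | drop)


def encode_joint_design(table: GenotypeTable, marker_index: int) -> JointDesign:
    """Build the (contrast, total) regressors for one marker.

    Raises :class:`ValidationError` if every call is missing (degenerate
    design; callers skip the marker and log the reason).
    """
    if not (0 <= marker_index < table.n_markers):
        raise IndexError(marker_index)
    usable = ~table.missing[marker_index]
    if not usable.any():
        raise ValidationError(
            f"marker {table.markers['marker_id'].iloc[marker_index]!r}: all calls missing"
        )
    a = table.a[marker_index].astype(float)
    b = table.b[marker_index].astype(float)
    contrast = np.where(usable, a - b, np.nan)
    total = np.where(usable, a + b, np.nan)
    return JointDesign(
        marker_id=str(table.markers["marker_id"].iloc[marker_index]),
        contrast=contrast,
        total=total,
        usable_mask=usable,
    )


def marker_frequencies(design: JointDesign) -> tuple[float, float]:
    """Minor-allele frequency over all copies, and the CNV rate.

    maf = min(sum a, sum b) / sum(a+b) over usable samples (0 when no copies);
    cnv_rate = fraction of usable samples whose total copy number is not 2.
    """
    u = design.usable_mask
    if not u.any():
        raise ValidationError("no usable samples")
    total = design.total[u]
    contrast = design.contrast[u]
    copies = total.sum()
    if copies == 0:
        maf = 0.0
    else:
        n_a = (total + contrast).sum() / 2.0
        n_b = (total - contrast).sum() / 2.0
        maf = float(min(n_a, n_b) / copies)
    cnv_rate = float(np.mean(total != 2))
    return maf, cnv_rate


def qc_filter(
    table: GenotypeTable, min_call_rate: float = 0.95, min_maf: float = 0.01
) -> GenotypeTable:
    """Drop markers below the call-rate or minor-allele-frequency thresholds.

    Thresholds are inclusive to pass (a marker is removed when its statistic
    is strictly below the threshold).  Removal counts per criterion are
    logged.
    """
    for name, v in (("min_call_rate", min_call_rate), ("min_maf", min_maf)):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"{name}={v} outside [0, 1]")
    usable = ~table.missing
    call_rate = usable.mean(axis=1) if table.n_samples else np.ones(table.n_markers)
    a = np.where(usable, table.a, 0).astype(float)
    b = np.where(usable, table.b, 0).astype(float)
    n_a, n_b = a.sum(axis=1), b.sum(axis=1)
    copies = n_a + n_b
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(copies > 0, np.minimum(n_a, n_b) / np.where(copies > 0, copies, 1), 0.0)
    fail_cr = call_rate < min_call_rate
    fail_maf = maf < min_maf
    keep = ~(fail_cr | fail_maf)
    logger.info(
        "qc filter: %d markers removed by call rate < %g, %d by maf < %g, %d kept",
        int(fail_cr.sum()), min_call_rate, int((fail_maf & ~fail_cr).sum()),
        min_maf, int(keep.sum()),
    )
    return table.subset_markers(np.flatnonzero(keep))
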