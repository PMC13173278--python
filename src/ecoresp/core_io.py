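"""Domain types, table/metadata I/O and shared statistical utilities.

The central observational object is the :class:`OguCountTable`, a dense
samples x OGUs abundance matrix (raw counts or relative abundances) with
ordered, unique sample and OGU identifiers.  Two on-disk dialects are
supported: a dense TSV (first column ``sample_id``, remaining columns OGU
ids) and a BIOM-like sparse triplet TSV (``sample_id``, ``ogu_id``,
``value``).  Sample and OGU metadata travel as one-row-per-entity TSVs.

Shared statistics used throughout the pipeline live here as thin,
contract-enforcing wrappers over scipy/statsmodels: Benjamini-Hochberg
adjustment, Spearman rank correlation and the Wilcoxon rank-sum test.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

SCHEMA_VERSION = "1.0"

#: tolerance for the row-sum invariant of relative-abundance tables
ROW_SUM_TOL = 1e-9

VALID_SOURCE_FLAGS = frozenset({"oral", "skin", "vagina", "food"})


class IntegrityError(ValueError):
    """Raised when a table or metadata collection violates an invariant."""


class TableParseError(ValueError):
    """Raised when an on-disk table cannot be parsed, naming the offending cell."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class OguCountTable:
    """Samples x OGUs abundance matrix.

    Parameters
    ----------
    sample_ids, ogu_ids:
        Ordered, unique identifiers aligned with the rows / columns of
        ``values``.
    values:
        Non-negative matrix, shape ``(n_samples, n_ogus)``.  Raw counts or
        relative abundances, depending on ``is_relative``.
    is_relative:
        If True every row must sum to 1 within ``ROW_SUM_TOL``.
    """

    sample_ids: list[str]
    ogu_ids: list[str]
    values: np.ndarray
    is_relative: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.ogu_ids = [str(o) for o in self.ogu_ids]
        if self.values.ndim != 2:
            raise IntegrityError("values must be a 2-D matrix")
        n, m = self.values.shape
        if n != len(self.sample_ids) or m != len(self.ogu_ids):
            raise IntegrityError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.ogu_ids)} OGUs"
            )
        for name, ids in (("sample", self.sample_ids), ("ogu", self.ogu_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise IntegrityError(f"duplicate {name} ids: {dupes}")
        if not np.all(np.isfinite(self.values)):
            raise IntegrityError("non-finite abundance values")
        if (self.values < 0).any():
            raise IntegrityError("negative abundance values")
        if self.is_relative:
            sums = self.values.sum(axis=1)
            bad = np.abs(sums - 1.0) > ROW_SUM_TOL
            if bad.any():
                ids = [self.sample_ids[i] for i in np.flatnonzero(bad)[:5]]
                raise IntegrityError(f"relative rows do not sum to 1: {ids}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_ogus(self) -> int:
        return len(self.ogu_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.ogu_ids)

    def sample_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.sample_ids)}

    def ogu_index(self) -> dict[str, int]:
        return {o: j for j, o in enumerate(self.ogu_ids)}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OguCountTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.ogu_ids == other.ogu_ids
            and self.is_relative == other.is_relative
            and np.allclose(self.values, other.values, rtol=0, atol=1e-12)
        )


@dataclass(frozen=True)
class SampleMetadata:
    """Clinical record for one stool metagenome sample."""

    sample_id: str
    dataset_id: str
    response: str  # "R" or "NR"
    cancer_type: str = "melanoma"
    age: float | None = None
    gender: str | None = None

    def __post_init__(self) -> None:
        if self.response not in ("R", "NR"):
            raise IntegrityError(
                f"sample {self.sample_id}: response must be R or NR, got {self.response!r}"
            )


@dataclass(frozen=True)
class OguMetadata:
    """Per-genome annotation attached to an OGU (taxonomy, quality, origin)."""

    ogu_id: str
    taxonomy: str = ""
    completeness: float = 100.0
    contamination: float = 0.0
    source_flags: frozenset[str] = frozenset()
    gene_families: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 100.0:
            raise IntegrityError(f"{self.ogu_id}: completeness outside [0, 100]")
        if self.contamination < 0:
            raise IntegrityError(f"{self.ogu_id}: negative contamination")
        object.__setattr__(self, "source_flags", frozenset(self.source_flags))
        unknown = self.source_flags - VALID_SOURCE_FLAGS
        if unknown:
            raise IntegrityError(f"{self.ogu_id}: unknown source flags {sorted(unknown)}")
        if self.gene_families is not None:
            object.__setattr__(self, "gene_families", frozenset(self.gene_families))

    def phylum(self) -> str | None:
        """Extract the phylum from a GTDB-style ``p__`` rank, if present."""
        for part in self.taxonomy.split(";"):
            part = part.strip()
            if part.startswith("p__"):
                return part[3:] or None
        return None


@dataclass(frozen=True)
class PrevalenceProfile:
    """Detection bookkeeping for one OGU.

    ``sample_prevalence`` is the occupancy count (samples with abundance
    strictly above the detection threshold); ``dataset_prevalence`` counts
    datasets contributing at least one detected sample.
    """

    ogu_id: str
    sample_prevalence: int
    sample_prevalence_frac: float
    dataset_prevalence: int
    mean_relabund: float


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

_DIALECTS = ("tsv_dense", "biom_triplet")


def _check_dialect(dialect: str) -> None:
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")


def read_ogu_table(path: str | Path, dialect: str = "tsv_dense") -> OguCountTable:
    """Read an abundance table, preserving file order of ids.

    Duplicate sample or OGU ids are an integrity error; a malformed numeric
    cell raises :class:`TableParseError` naming the row and column.
    """
    _check_dialect(dialect)
    path = Path(path)
    if dialect == "tsv_dense":
        raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
        ogu_ids = list(raw.columns)
        sample_ids = [str(s) for s in raw.index]
        values = np.empty(raw.shape, dtype=float)
        for j, ogu in enumerate(ogu_ids):
            col = raw[ogu]
            try:
                values[:, j] = col.astype(float)
            except ValueError:
                for i, cell in enumerate(col):
                    try:
                        float(cell)
                    except (TypeError, ValueError):
                        raise TableParseError(
                            f"{path}: cannot parse value {cell!r} at "
                            f"sample {sample_ids[i]!r}, OGU {ogu!r}"
                        ) from None
                raise
        return OguCountTable(sample_ids, ogu_ids, values)

    raw = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "ogu_id": str})
    required = {"sample_id", "ogu_id", "value"}
    if not required.issubset(raw.columns):
        raise TableParseError(f"{path}: triplet file must have columns {sorted(required)}")
    try:
        vals = raw["value"].astype(float)
    except ValueError:
        bad = raw.loc[pd.to_numeric(raw["value"], errors="coerce").isna()].iloc[0]
        raise TableParseError(
            f"{path}: cannot parse value {bad['value']!r} at "
            f"sample {bad['sample_id']!r}, OGU {bad['ogu_id']!r}"
        ) from None
    sample_ids = list(dict.fromkeys(raw["sample_id"]))
    ogu_ids = list(dict.fromkeys(raw["ogu_id"]))
    if raw.duplicated(["sample_id", "ogu_id"]).any():
        raise IntegrityError(f"{path}: duplicate (sample, OGU) triplet entries")
    si = {s: i for i, s in enumerate(sample_ids)}
    oi = {o: j for j, o in enumerate(ogu_ids)}
    values = np.zeros((len(sample_ids), len(ogu_ids)))
    values[raw["sample_id"].map(si), raw["ogu_id"].map(oi)] = vals
    return OguCountTable(sample_ids, ogu_ids, values)


def write_ogu_table(table: OguCountTable, path: str | Path, dialect: str = "tsv_dense") -> None:
    _check_dialect(dialect)
    path = Path(path)
    if dialect == "tsv_dense":
        df = table.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")
        return
    # registration block (first sample x all OGUs, all samples x first OGU,
    # zeros included) pins the id order so the sparse dialect round-trips
    # exactly; the remaining block holds only nonzero cells
    recs: list[tuple[str, str, float]] = []
    for j, ogu in enumerate(table.ogu_ids):
        recs.append((table.sample_ids[0], ogu, table.values[0, j]))
    for i in range(1, table.n_samples):
        recs.append((table.sample_ids[i], table.ogu_ids[0], table.values[i, 0]))
    rows, cols = np.nonzero(table.values[1:, 1:])
    for i, j in zip(rows, cols):
        recs.append(
            (table.sample_ids[i + 1], table.ogu_ids[j + 1], table.values[i + 1, j + 1])
        )
    pd.DataFrame(recs, columns=["sample_id", "ogu_id", "value"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# metadata I/O
# ---------------------------------------------------------------------------


def read_sample_metadata(path: str | Path) -> dict[str, SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, SampleMetadata] = {}
    for _, row in df.iterrows():
        sid = row["sample_id"]
        if sid in out:
            raise IntegrityError(f"duplicate sample metadata record for {sid!r}")
        age = row.get("age")
        out[sid] = SampleMetadata(
            sample_id=sid,
            dataset_id=row["dataset_id"],
            response=row["response"],
            cancer_type=row.get("cancer_type", "melanoma") or "melanoma",
            age=float(age) if age not in (None, "", "NA") and not pd.isna(age) else None,
            gender=row.get("gender") if not pd.isna(row.get("gender")) else None,
        )
    return out


def write_sample_metadata(meta: Mapping[str, SampleMetadata], path: str | Path) -> None:
    rows = [dataclasses.asdict(m) for m in meta.values()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ogu_metadata(path: str | Path) -> dict[str, OguMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, OguMetadata] = {}
    for _, row in df.iterrows():
        oid = row["ogu_id"]
        if oid in out:
            raise IntegrityError(f"duplicate OGU metadata record for {oid!r}")
        flags = row.get("source_flags")
        fams = row.get("gene_families")
        out[oid] = OguMetadata(
            ogu_id=oid,
            taxonomy=row.get("taxonomy", "") if not pd.isna(row.get("taxonomy")) else "",
            completeness=float(row.get("completeness", 100.0)),
            contamination=float(row.get("contamination", 0.0)),
            source_flags=frozenset(
                f for f in str(flags).split(";") if f and f != "nan"
            )
            if flags is not None and not pd.isna(flags)
            else frozenset(),
            gene_families=frozenset(
                f for f in str(fams).split(";") if f and f != "nan"
            )
            if fams is not None and not pd.isna(fams)
            else None,
        )
    return out


def write_ogu_metadata(meta: Mapping[str, OguMetadata], path: str | Path) -> None:
    rows = []
    for m in meta.values():
        rows.append(
            {
                "ogu_id": m.ogu_id,
                "taxonomy": m.taxonomy,
                "completeness": m.completeness,
                "contamination": m.contamination,
                "source_flags": ";".join(sorted(m.source_flags)),
                "gene_families": ";".join(sorted(m.gene_families))
                if m.gene_families is not None
                else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# normalization and prevalence
# ---------------------------------------------------------------------------


def tss_normalize(table: OguCountTable) -> OguCountTable:
    """Total-sum scaling: divide each row by its sum.  Idempotent.

    All-zero rows are an explicit error (the resulting composition would be
    undefined), reported with the offending sample ids.
    """
    sums = table.values.sum(axis=1)
    zero = sums <= 0
    if zero.any():
        ids = [table.sample_ids[i] for i in np.flatnonzero(zero)]
        raise IntegrityError(f"all-zero sample rows cannot be normalized: {ids}")
    return OguCountTable(
        list(table.sample_ids),
        list(table.ogu_ids),
        table.values / sums[:, None],
        is_relative=True,
    )


def compute_prevalence(
    table: OguCountTable,
    meta: Mapping[str, SampleMetadata],
    detection_threshold: float = 0.0,
) -> dict[str, PrevalenceProfile]:
    """Per-OGU occupancy bookkeeping.

    Detection means abundance strictly greater than ``detection_threshold``
    (default 0: any positive abundance counts).  ``dataset_prevalence``
    counts datasets with at least one detected sample; ``mean_relabund``
    averages relative abundance over all samples (the table is TSS-normalized
    internally if it holds raw counts).
    """
    if detection_threshold < 0:
        raise ValueError("detection_threshold must be >= 0")
    missing = [s for s in table.sample_ids if s not in meta]
    if missing:
        raise IntegrityError(f"samples without metadata: {missing[:5]}")
    rel = table if table.is_relative else tss_normalize(table)
    detected = table.values > detection_threshold
    datasets = np.asarray([meta[s].dataset_id for s in table.sample_ids])
    uniq = list(dict.fromkeys(datasets))
    n = table.n_samples
    sample_prev = detected.sum(axis=0)
    ds_prev = np.zeros(table.n_ogus, dtype=int)
    for d in uniq:
        ds_prev += detected[datasets == d].any(axis=0)
    mean_rel = rel.values.mean(axis=0)
    return {
        ogu: PrevalenceProfile(
            ogu_id=ogu,
            sample_prevalence=int(sample_prev[j]),
            sample_prevalence_frac=float(sample_prev[j] / n),
            dataset_prevalence=int(ds_prev[j]),
            mean_relabund=float(mean_rel[j]),
        )
        for j, ogu in enumerate(table.ogu_ids)
    }


# ---------------------------------------------------------------------------
# shared statistics
# ---------------------------------------------------------------------------


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The p-value uses scipy's large-sample t approximation.  A constant input
    vector leaves the correlation undefined and raises ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman rho undefined for a constant vector")
    rho, p = _sps.spearmanr(x, y)
    return float(rho), float(p)


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution for small tie-free samples, the normal
    approximation with tie correction otherwise (scipy's ``method='auto'``).
    Returns ``(U statistic, p)``; identical constant samples give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if np.ptp(np.concatenate([a, b])) == 0:
        return float(a.size * b.size / 2.0), 1.0
    res = _sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# result serialization
# ---------------------------------------------------------------------------


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def result_to_json(result, path: str | Path | None = None) -> str:
    """Serialize a result object to JSON with a ``schema_version`` field."""
    payload = {"schema_version": SCHEMA_VERSION, "result": _jsonable(result)}
    text = json.dumps(payload, indent=2, allow_nan=True)
    if path is not None:
        Path(path).write_text(text)
    return text
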