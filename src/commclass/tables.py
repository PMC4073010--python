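"""Genus-level abundance tables and their normalisations.

The pipeline's entry point is a samples-by-genera table of 16S read
counts.  Three transforms are provided:

* copy-number scaling — divide each genus's reads by the genus's average
  16S rRNA gene copy number, so multi-copy taxa are not over-counted;
* proportion transform — row-normalise to relative abundances, the input
  to the Bray-Curtis dissimilarity;
* rarefaction — subsample every sample without replacement to a common
  read depth, the input to Shannon-diversity estimation.

Copy-number-scaled proportions feed clustering; rarefied raw counts feed
diversity.  The two normalisation paths are deliberately kept separate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "ParseError",
    "CountTable",
    "AbundanceTable",
    "ProportionTable",
    "CopyNumberMap",
    "read_count_table",
    "write_count_table",
    "read_copy_numbers",
    "scale_by_copy_number",
    "to_proportions",
    "rarefy",
]


class ValidationError(ValueError):
    """An input violates a documented invariant."""


class ParseError(ValueError):
    """A file cannot be interpreted as the expected tab-delimited table."""


def _check_ids(ids: list[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class CountTable:
    """Integer genus-by-sample read counts (rows = samples, columns = taxa)."""

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValidationError("counts must be integers")
            counts = np.round(counts).astype(np.int64)
        if (counts < 0).any():
            i, k = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count for sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[k]!r}"
            )
        _check_ids(self.sample_ids, "sample")
        _check_ids(self.taxon_ids, "taxon")
        self.counts = counts.astype(np.int64)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.sample_ids, columns=self.taxon_ids
        )

    def subset(self, sample_ids: list[str]) -> "CountTable":
        """Restrict to the given samples, preserving the given order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return CountTable(list(sample_ids), list(self.taxon_ids), self.counts[idx])


@dataclass
class AbundanceTable:
    """Real-valued genus-by-sample abundances (e.g. copy-number-scaled counts)."""

    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError("values shape does not match id lists")
        if (values < 0).any():
            raise ValidationError("abundances must be non-negative")
        _check_ids(self.sample_ids, "sample")
        _check_ids(self.taxon_ids, "taxon")
        self.values = values

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.taxon_ids
        )


@dataclass
class ProportionTable:
    """Per-sample relative abundances; every row sums to 1."""

    sample_ids: list[str]
    taxon_ids: list[str]
    proportions: np.ndarray

    _ROW_SUM_TOL = 1e-9

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        p = np.asarray(self.proportions, dtype=float)
        if p.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError("proportions shape does not match id lists")
        if (p < 0).any() or (p > 1 + self._ROW_SUM_TOL).any():
            raise ValidationError("proportions must lie in [0, 1]")
        sums = p.sum(axis=1)
        bad = np.abs(sums - 1.0) > self._ROW_SUM_TOL
        if bad.any():
            i = int(np.argmax(bad))
            raise ValidationError(
                f"row for sample {self.sample_ids[i]!r} sums to {sums[i]!r}, not 1"
            )
        _check_ids(self.sample_ids, "sample")
        _check_ids(self.taxon_ids, "taxon")
        self.proportions = p

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.proportions, index=self.sample_ids, columns=self.taxon_ids
        )

    def subset(self, sample_ids: list[str]) -> "ProportionTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return ProportionTable(
            list(sample_ids), list(self.taxon_ids), self.proportions[idx]
        )


@dataclass
class CopyNumberMap:
    """Genus label -> average 16S rRNA gene copy number (all positive)."""

    copy_numbers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for genus, cn in self.copy_numbers.items():
            cn = float(cn)
            if not cn > 0:
                raise ValidationError(
                    f"copy number for {genus!r} must be positive, got {cn}"
                )
            clean[str(genus)] = cn
        self.copy_numbers = clean

    def get(self, genus: str, default: float) -> float:
        return self.copy_numbers.get(genus, default)

    def __contains__(self, genus: str) -> bool:
        return genus in self.copy_numbers


def read_count_table(path) -> CountTable:
    """Read a tab-delimited samples-by-taxa count table.

    First row holds taxon labels, first column the sample ids.  Any
    non-numeric or negative cell raises an error naming the offending
    sample and taxon.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot read {path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate sample identifier: {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValidationError(f"duplicate taxon identifier: {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().values.any():
        i, k = np.argwhere(numeric.isna().values)[0]
        raise ParseError(
            f"non-numeric cell at sample {df.index[i]!r}, taxon {df.columns[k]!r}: "
            f"{df.iat[i, k]!r}"
        )
    return CountTable(list(df.index), list(df.columns), numeric.to_numpy())


def write_count_table(table: CountTable, path) -> None:
    """Write the canonical tab-delimited form (round-trips byte-stably)."""
    df = table.to_dataframe()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_copy_numbers(path) -> CopyNumberMap:
    """Read a two-column tab-delimited (genus, copy_number) file.

    A header row is detected by a non-numeric second field and skipped.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] != 2:
        raise ParseError(f"{path}: expected 2 columns, found {df.shape[1]}")
    first_val = pd.to_numeric(df.iloc[0, 1], errors="coerce")
    if pd.isna(first_val):
        df = df.iloc[1:]
    values = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if values.isna().any():
        row = df.iloc[int(np.argmax(values.isna().values))]
        raise ParseError(f"non-numeric copy number for genus {row.iloc[0]!r}")
    return CopyNumberMap(dict(zip(df.iloc[:, 0], values)))


def scale_by_copy_number(
    table: CountTable, copy_numbers: CopyNumberMap, default: float = 1.0
) -> AbundanceTable:
    """Divide each genus's counts by its average 16S copy number.

    Genera missing from the map fall back to ``default`` (1.0 leaves
    them unscaled) and are logged.
    """
    if not default > 0:
        raise ValidationError(f"default copy number must be positive, got {default}")
    divisors = np.array(
        [copy_numbers.get(t, default) for t in table.taxon_ids], dtype=float
    )
    missing = [t for t in table.taxon_ids if t not in copy_numbers]
    for genus in missing:
        logger.info(
            "no copy number for genus %r; using default %.3g", genus, default
        )
    return AbundanceTable(
        list(table.sample_ids),
        list(table.taxon_ids),
        table.counts / divisors[np.newaxis, :],
    )


def to_proportions(table: CountTable | AbundanceTable) -> ProportionTable:
    """Row-normalise a (possibly scaled) abundance table to proportions."""
    values = (
        table.counts.astype(float)
        if isinstance(table, CountTable)
        else table.values
    )
    totals = values.sum(axis=1)
    if (totals <= 0).any():
        i = int(np.argmax(totals <= 0))
        raise ValidationError(
            f"sample {table.sample_ids[i]!r} has zero total abundance"
        )
    return ProportionTable(
        list(table.sample_ids), list(table.taxon_ids), values / totals[:, np.newaxis]
    )


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped and logged.  The
    draw is multivariate hypergeometric and deterministic given ``seed``.
    """
    if depth < 1:
        raise ValidationError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    keep_ids: list[str] = []
    rows: list[np.ndarray] = []
    dropped: list[str] = []
    for sid, row in zip(table.sample_ids, table.counts):
        total = int(row.sum())
        if total < depth:
            dropped.append(sid)
            continue
        if total == depth:
            rows.append(row.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
        keep_ids.append(sid)
    if dropped:
        logger.info(
            "rarefaction to %d dropped %d sample(s): %s",
            depth,
            len(dropped),
            ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
        )
    if not keep_ids:
        raise ValidationError(f"no sample reaches rarefaction depth {depth}")
    return CountTable(
        keep_ids, list(table.taxon_ids), np.vstack(rows).astype(np.int64)
    )
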