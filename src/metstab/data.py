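"""Data model, I/O, validation and aggregation for balanced MET plot data.

A multi-environment trial (MET) evaluates ``G`` genotypes in ``E``
environments under a randomized complete block design with ``R``
replicates (blocks) nested within each environment.  The long (tidy)
plot-level table — one row per (environment, genotype, replicate) with
one column per trait — is the single canonical format; every wide
genotype-by-environment matrix downstream is derived from it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "METDataset",
    "TraitMatrix",
    "SummaryStats",
    "BalanceReport",
    "METSchemaError",
    "DesignError",
    "read_met_csv",
    "write_met_csv",
    "validate_design",
    "ge_means",
    "summary_stats",
    "DEFAULT_TRAITS",
]

#: Trait profile of the horse gram trials this package was built around:
#: days to maturity, clusters/plant, pods/plant, pods/cluster, seeds/pod
#: and seed yield (kg/ha).
DEFAULT_TRAITS = ("DM", "NC", "NP", "NPC", "NS", "YD")

ENV_COL, GEN_COL, REP_COL = "ENV", "GEN", "REP"
_KEY_COLS = [ENV_COL, GEN_COL, REP_COL]


class METSchemaError(ValueError):
    """Input table violates the expected MET schema."""


class DesignError(ValueError):
    """Operation requires a balanced design and the data are not balanced."""


@dataclass(frozen=True)
class SummaryStats:
    """Location/spread summary of a vector (sample n-1 estimators)."""

    mean: float
    minimum: float
    maximum: float
    sd: float
    cv_percent: float


@dataclass(frozen=True)
class BalanceReport:
    """Balance diagnosis of a MET dataset."""

    n_genotypes: int
    n_environments: int
    n_replicates: int
    balanced: bool
    missing_cells: tuple[tuple[str, str, str], ...] = ()
    duplicates: tuple[tuple[str, str, str], ...] = ()


@dataclass(frozen=True)
class TraitMatrix:
    """Genotype x environment table of replicate means for one trait."""

    trait: str
    values: pd.DataFrame  # index: genotypes, columns: environments

    @property
    def genotypes(self) -> list[str]:
        return list(self.values.index)

    @property
    def environments(self) -> list[str]:
        return list(self.values.columns)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


@dataclass
class METDataset:
    """Long-format balanced MET plot records.

    Parameters
    ----------
    table
        DataFrame with columns ``ENV``, ``GEN``, ``REP`` and one numeric
        column per trait; exactly one row per (ENV, GEN, REP).
    traits
        Ordered trait names; defaults to the numeric columns after the
        three key columns, in table order.
    """

    table: pd.DataFrame
    traits: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        missing = [c for c in _KEY_COLS if c not in self.table.columns]
        if missing:
            raise METSchemaError(f"missing required column(s): {missing}")
        if not self.traits:
            self.traits = tuple(
                c for c in self.table.columns if c not in _KEY_COLS
            )
        absent = [t for t in self.traits if t not in self.table.columns]
        if absent:
            raise METSchemaError(f"trait column(s) not in table: {absent}")
        for t in self.traits:
            col = pd.to_numeric(self.table[t], errors="coerce")
            bad = self.table.index[col.isna() | ~np.isfinite(col)]
            if len(bad):
                raise METSchemaError(
                    f"non-numeric or non-finite value in trait {t!r} "
                    f"at row(s) {list(bad[:5])}"
                )
            self.table[t] = col.astype(float)
        self.table = self.table.reset_index(drop=True)

    # -- design constants ------------------------------------------------
    @property
    def genotypes(self) -> list[str]:
        return sorted(self.table[GEN_COL].astype(str).unique())

    @property
    def environments(self) -> list[str]:
        return sorted(self.table[ENV_COL].astype(str).unique())

    @property
    def replicates(self) -> list[str]:
        return sorted(self.table[REP_COL].astype(str).unique())

    @property
    def design(self) -> tuple[int, int, int]:
        """(G genotypes, E environments, R replicates)."""
        return (
            len(self.genotypes),
            len(self.environments),
            len(self.replicates),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, METDataset):
            return NotImplemented
        if self.traits != other.traits:
            return False
        a = self.table.sort_values(_KEY_COLS).reset_index(drop=True)
        b = other.table.sort_values(_KEY_COLS).reset_index(drop=True)
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        if not a[_KEY_COLS].astype(str).equals(b[_KEY_COLS].astype(str)):
            return False
        return bool(
            np.allclose(
                a[list(self.traits)].to_numpy(float),
                b[list(self.traits)].to_numpy(float),
                rtol=0,
                atol=1e-12,
            )
        )


def read_met_csv(
    source: str | IO[str], traits: Sequence[str] | None = None
) -> METDataset:
    """Read a long-format MET CSV (columns ENV, GEN, REP, traits...).

    ``source`` may be a path or an open text stream.  If ``traits`` is
    omitted, every column after the three key columns is a trait.
    Raises :class:`METSchemaError` on missing columns or non-numeric
    trait cells, and on duplicated (ENV, GEN, REP) keys.
    """
    df = pd.read_csv(source, dtype=str)
    missing = [c for c in _KEY_COLS if c not in df.columns]
    if missing:
        raise METSchemaError(f"missing required column(s): {missing}")
    if traits is not None:
        absent = [t for t in traits if t not in df.columns]
        if absent:
            raise METSchemaError(f"trait column(s) not in file: {absent}")
        df = df[_KEY_COLS + list(traits)]
    dup = df.duplicated(subset=_KEY_COLS, keep=False)
    if dup.any():
        keys = df.loc[dup, _KEY_COLS].drop_duplicates().to_records(index=False)
        raise METSchemaError(
            f"duplicate (ENV, GEN, REP) record(s): {list(keys)[:5]}"
        )
    return METDataset(df, tuple(traits) if traits is not None else ())


def write_met_csv(data: METDataset, target: str | IO[str]) -> None:
    """Write the dataset in the canonical long CSV dialect."""
    cols = _KEY_COLS + list(data.traits)
    data.table[cols].to_csv(target, index=False)


def validate_design(data: METDataset) -> BalanceReport:
    """Diagnose balance: one record per (environment, genotype, replicate).

    Purely reporting — never raises; downstream closed-form operations
    reject unbalanced data themselves.
    """
    keys = data.table[_KEY_COLS].astype(str)
    counts = keys.value_counts()
    dups = tuple(k for k, n in counts.items() if n > 1)
    envs, gens, reps = data.environments, data.genotypes, data.replicates
    have = set(map(tuple, keys.to_numpy()))
    missing = tuple(
        (e, g, r)
        for e in envs
        for g in gens
        for r in reps
        if (e, g, r) not in have
    )
    balanced = not dups and not missing and len(data.table) == len(envs) * len(
        gens
    ) * len(reps)
    return BalanceReport(
        n_genotypes=len(gens),
        n_environments=len(envs),
        n_replicates=len(reps),
        balanced=balanced,
        missing_cells=missing,
        duplicates=dups,
    )


def require_balanced(data: METDataset) -> None:
    report = validate_design(data)
    if not report.balanced:
        raise DesignError(
            f"balanced design required: {len(report.missing_cells)} missing "
            f"cell(s), {len(report.duplicates)} duplicate(s)"
        )


def ge_means(data: METDataset, trait: str) -> TraitMatrix:
    """Genotype-by-environment cell means (averaged over replicates)."""
    if trait not in data.traits:
        raise KeyError(f"unknown trait {trait!r}; have {list(data.traits)}")
    require_balanced(data)
    wide = (
        data.table.groupby([GEN_COL, ENV_COL], sort=True)[trait]
        .mean()
        .unstack(ENV_COL)
    )
    wide.index = wide.index.astype(str)
    wide.columns = wide.columns.astype(str)
    return TraitMatrix(trait=trait, values=wide)


def summary_stats(values: Iterable[float]) -> SummaryStats:
    """Mean, min, max, sample SD and CV% of a vector (matches trial
    summary rows: CV% = 100 * sd / mean)."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("summary_stats requires at least 2 values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if mean == 0.0:
        raise ZeroDivisionError("CV undefined: mean is 0")
    return SummaryStats(
        mean=mean,
        minimum=float(x.min()),
        maximum=float(x.max()),
        sd=sd,
        cv_percent=100.0 * sd / mean,
    )


def matrix_to_csv(matrix: TraitMatrix) -> str:
    """Cell means as CSV text, genotypes as rows and environments as
    columns (the export dialect for external biplotting)."""
    buf = io.StringIO()
    matrix.values.to_csv(buf, index_label=GEN_COL)
    return buf.getvalue()
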