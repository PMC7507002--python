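"""Core data containers: expression matrix, survival and clinical tables.

All three are thin, validated wrappers around :class:`pandas.DataFrame`
with round-trip TSV IO matching the package's plain-text interchange
formats (expression: genes x samples, first column ``gene``; survival:
``sample, time, event``; clinical: ``sample, covariate``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InputError, MissingGeneError


@dataclass
class ExpressionMatrix:
    """Gene-by-sample matrix of normalized log-scale expression.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by unique gene symbols, columns by unique sample IDs,
        all values finite. Rank correlation downstream needs at least four
        samples.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise InputError(f"duplicate gene symbols: {dup[:5]}")
        if cols.has_duplicates:
            raise InputError("duplicate sample IDs")
        if self.data.shape[1] < 4:
            raise InputError(
                f"need >= 4 samples for rank correlation, got {self.data.shape[1]}"
            )
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise InputError("expression values must all be finite")

    @property
    def genes(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def __contains__(self, gene: str) -> bool:
        return gene in self.data.index

    def vector(self, gene: str) -> np.ndarray:
        """Expression vector of one gene across samples."""
        if gene not in self.data.index:
            raise MissingGeneError(gene)
        return self.data.loc[gene].to_numpy(dtype=float)

    def require(self, genes) -> None:
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise MissingGeneError(missing)

    def subset(self, genes) -> "ExpressionMatrix":
        self.require(genes)
        return ExpressionMatrix(self.data.loc[list(genes)])

    def to_tsv(self, path) -> None:
        self.data.rename_axis("gene").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df)


@dataclass
class SurvivalTable:
    """Right-censored survival outcomes: one (time, event) pair per sample.

    ``event`` is 1 for an observed death/event and 0 for censoring; all
    times must be strictly positive.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"sample", "time", "event"}
        if not required.issubset(self.data.columns):
            raise InputError(
                f"survival table needs columns {sorted(required)}, "
                f"got {self.data.columns.tolist()}"
            )
        if self.data["sample"].duplicated().any():
            raise InputError("duplicate sample IDs in survival table")
        t = self.data["time"].to_numpy(dtype=float)
        if not (np.isfinite(t).all() and (t > 0).all()):
            raise InputError("survival times must be finite and > 0")
        e = self.data["event"].to_numpy()
        if not np.isin(e, [0, 1]).all():
            raise InputError("event indicator must be 0 or 1")

    @property
    def samples(self) -> list[str]:
        return self.data["sample"].tolist()

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def __len__(self) -> int:
        return len(self.data)

    def align(self, sample_ids) -> "SurvivalTable":
        """Reorder to ``sample_ids``, raising with counts of unmatched IDs."""
        sample_ids = list(sample_ids)
        indexed = self.data.set_index("sample")
        missing = [s for s in sample_ids if s not in indexed.index]
        if missing:
            raise InputError(
                f"{len(missing)} sample ID(s) have no survival record "
                f"(e.g. {missing[:3]})"
            )
        out = indexed.loc[sample_ids].reset_index()
        return SurvivalTable(out)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SurvivalTable":
        df = pd.read_csv(path, sep="\t", dtype={"sample": str})
        return cls(df)

    @classmethod
    def from_arrays(cls, samples, time, event) -> "SurvivalTable":
        return cls(
            pd.DataFrame(
                {
                    "sample": list(samples),
                    "time": np.asarray(time, dtype=float),
                    "event": np.asarray(event, dtype=int),
                }
            )
        )


@dataclass
class ClinicalTable:
    """One binary clinical covariate per sample (e.g. nodal invasion, ER status)."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"sample", "covariate"}
        if not required.issubset(self.data.columns):
            raise InputError(
                f"clinical table needs columns {sorted(required)}, "
                f"got {self.data.columns.tolist()}"
            )
        if self.data["sample"].duplicated().any():
            raise InputError("duplicate sample IDs in clinical table")
        c = self.data["covariate"].to_numpy()
        if not np.isin(c, [0, 1]).all():
            raise InputError("clinical covariate must be binary 0/1")

    @property
    def samples(self) -> list[str]:
        return self.data["sample"].tolist()

    @property
    def covariate(self) -> np.ndarray:
        return self.data["covariate"].to_numpy(dtype=int)

    def align(self, sample_ids) -> "ClinicalTable":
        sample_ids = list(sample_ids)
        indexed = self.data.set_index("sample")
        missing = [s for s in sample_ids if s not in indexed.index]
        if missing:
            raise InputError(
                f"{len(missing)} sample ID(s) have no clinical record "
                f"(e.g. {missing[:3]})"
            )
        return ClinicalTable(indexed.loc[sample_ids].reset_index())

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ClinicalTable":
        df = pd.read_csv(path, sep="\t", dtype={"sample": str})
        return cls(df)


def read_gene_list(path) -> list[str]:
    """Read a one-symbol-per-line gene list, ignoring blanks and ``#`` comments."""
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                out.append(sym)
    return out
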