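"""In-memory containers shared across pipeline stages.

The numeric payloads are plain pandas objects (genes as rows, samples as
columns); the wrappers add the bookkeeping each stage's contract needs:
per-sample library sizes and filter provenance for counts, an explicit
transform chain for expression values, and labeled symmetric distances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd


class DataError(ValueError):
    """Raised for malformed numeric inputs."""


@dataclass
class CountMatrix:
    """Gene x sample read-pair counts with per-sample library sizes.

    ``library_size`` is the number of retained read pairs per sample (which
    may exceed the column sum when pairs land outside any ORF).
    """

    counts: pd.DataFrame
    library_size: pd.Series
    provenance: dict[str, Any] = field(default_factory=dict)
    intergenic: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        self.library_size = self.library_size.reindex(self.counts.columns)
        if self.library_size.isna().any():
            missing = list(self.library_size.index[self.library_size.isna()])
            raise DataError(f"library_size missing for samples: {missing}")
        self.library_size = self.library_size.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise DataError("negative counts")
        colsums = self.counts.sum(axis=0)
        if (colsums > self.library_size).any():
            bad = list(colsums.index[colsums > self.library_size])
            raise DataError(f"column sums exceed library size for samples: {bad}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def drop_samples(self, samples: Sequence[str]) -> "CountMatrix":
        keep = [s for s in self.counts.columns if s not in set(samples)]
        return CountMatrix(
            counts=self.counts[keep].copy(),
            library_size=self.library_size[keep].copy(),
            provenance=dict(self.provenance, dropped_samples=list(samples)),
            intergenic=None if self.intergenic is None else self.intergenic[keep].copy(),
        )

    def write_tsv(self, path: str | Path) -> None:
        path = Path(path)
        self.counts.rename_axis("gene_id").to_csv(path, sep="\t")
        meta = {
            "library_size": {k: int(v) for k, v in self.library_size.items()},
            "provenance": self.provenance,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=1, sort_keys=True)
        )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CountMatrix":
        path = Path(path)
        counts = pd.read_csv(path, sep="\t", index_col=0)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            libsize = pd.Series(meta["library_size"]).reindex(counts.columns)
            provenance = meta.get("provenance", {})
        else:
            libsize = counts.sum(axis=0)
            provenance = {"library_size": "inferred from column sums"}
        return cls(counts=counts, library_size=libsize, provenance=provenance)


@dataclass
class ExpressionMatrix:
    """Real-valued gene x sample matrix tagged with its transform chain.

    Each applied transform appends ``(name, params)`` to ``transform_chain``
    so the values are fully reproducible from the source counts.
    """

    values: pd.DataFrame
    transform_chain: list[tuple[str, dict[str, Any]]] = field(default_factory=list)
    source: Optional[CountMatrix] = None

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def with_transform(
        self, values: pd.DataFrame, name: str, **params: Any
    ) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=values,
            transform_chain=self.transform_chain + [(name, params)],
            source=self.source,
        )

    def chain_names(self) -> list[str]:
        return [name for name, _ in self.transform_chain]

    def write_tsv(self, path: str | Path) -> None:
        path = Path(path)
        self.values.rename_axis("gene_id").to_csv(path, sep="\t", float_format="%.10g")
        sidecar = [{"transform": n, "params": p} for n, p in self.transform_chain]
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(sidecar, indent=1)
        )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        path = Path(path)
        values = pd.read_csv(path, sep="\t", index_col=0)
        chain: list[tuple[str, dict[str, Any]]] = []
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        if meta_path.exists():
            chain = [
                (d["transform"], d.get("params", {}))
                for d in json.loads(meta_path.read_text())
            ]
        return cls(values=values, transform_chain=chain)


@dataclass
class DistanceMatrix:
    """Symmetric sample x sample resemblance matrix with zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise DataError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise DataError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise DataError("distance matrix diagonal is not zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        from scipy.spatial.distance import squareform

        return squareform(self.d, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("sample").to_csv(
            path, sep="\t", float_format="%.10g"
        )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=[str(c) for c in df.columns], d=df.to_numpy())
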