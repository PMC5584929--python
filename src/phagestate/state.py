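"""Per-sample lytic vs lysogenic state calls from marker-gene expression.

The classifier compares transcription of the lytic marker (viral tail
sheath, gp091 by default) against the primary lysogeny marker (the IS607
transposase gp135); a serine recombinase (gp136) serves as the secondary
lysogeny marker. A sample whose log2 gp091:gp135 ratio is positive is
called lytic-dominated, negative lysogenic-dominated. Samples with
negligible phage and host expression are excluded before classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix, DataError, ExpressionMatrix


@dataclass(frozen=True)
class MarkerSet:
    """The marker genes driving the state call."""

    lytic_marker: str = "gp091"
    lysogeny_markers: tuple[str, ...] = ("gp135", "gp136")

    @property
    def primary_lysogeny_marker(self) -> str:
        return self.lysogeny_markers[0]

    @property
    def all(self) -> tuple[str, ...]:
        return (self.lytic_marker, *self.lysogeny_markers)

    def validate(self, genes: Sequence[str]) -> None:
        missing = [g for g in self.all if g not in set(genes)]
        if missing:
            raise DataError(f"marker genes missing from matrix: {missing}")


@dataclass(frozen=True)
class StateCall:
    sample: str
    log2_ratio: float
    state: str  # lytic | lysogenic | indeterminate | excluded
    exclusion_reason: Optional[str] = None


@dataclass(frozen=True)
class CorrelationResult:
    gene_a: str
    gene_b: str
    rho: float
    p_value: float
    n: int
    undefined: bool = False


def flag_negligible(
    counts: CountMatrix,
    phage_genes: Sequence[str],
    rpob_gene: str = "rpoB",
    min_total_pairs: int = 10,
) -> dict[str, list[str]]:
    """Samples with negligible phage and/or host expression.

    A sample is excluded iff its total phage-gene pair count is below
    ``min_total_pairs`` (strict less-than) or its rpoB count is zero.
    Returns {sample: [reasons]} for the excluded samples.
    """
    phage_genes = [g for g in phage_genes if g in counts.counts.index]
    phage_total = counts.counts.loc[phage_genes].sum(axis=0)
    out: dict[str, list[str]] = {}
    for s in counts.samples:
        reasons = []
        if phage_total[s] < min_total_pairs:
            reasons.append("negligible_phage_expression")
        if rpob_gene in counts.counts.index and counts.counts.at[rpob_gene, s] == 0:
            reasons.append("no_rpob_expression")
        if reasons:
            out[s] = reasons
    return out


def marker_log2_ratio(
    expr: ExpressionMatrix,
    markers: MarkerSet = MarkerSet(),
    lysogeny_marker: Optional[str] = None,
) -> pd.Series:
    """log2((lytic + eps) / (lysogeny + eps)) per sample.

    The pseudocount eps is half the smallest nonzero value in the matrix,
    so zero-vs-zero resolves to a ratio of exactly 0 and the ratio is
    invariant to the library-size scale only up to eps (which vanishes for
    expressed markers).
    """
    markers.validate(expr.genes)
    lys = lysogeny_marker or markers.primary_lysogeny_marker
    arr = expr.values.to_numpy()
    nonzero = arr[arr > 0]
    eps = 0.5 * nonzero.min() if nonzero.size else 1.0
    num = expr.values.loc[markers.lytic_marker] + eps
    den = expr.values.loc[lys] + eps
    return pd.Series(
        np.log2(num.to_numpy() / den.to_numpy()),
        index=expr.samples,
        name=f"log2_{markers.lytic_marker}_{lys}",
    )


def classify_state(
    expr: ExpressionMatrix,
    markers: MarkerSet = MarkerSet(),
    tie_band: float = 0.0,
    excluded: Optional[dict[str, list[str]]] = None,
) -> pd.DataFrame:
    """Call each sample lytic / lysogenic / indeterminate.

    lytic iff log2_ratio > tie_band, lysogenic iff < -tie_band,
    indeterminate within the band. Samples listed in ``excluded`` are
    reported as excluded with their reasons and no ratio.
    """
    if tie_band < 0:
        raise DataError("tie_band must be >= 0")
    excluded = excluded or {}
    ratio = marker_log2_ratio(expr, markers)
    rows = []
    for s in expr.samples:
        if s in excluded:
            rows.append(StateCall(s, float("nan"), "excluded", ";".join(excluded[s])))
            continue
        r = float(ratio[s])
        if r > tie_band:
            state = "lytic"
        elif r < -tie_band:
            state = "lysogenic"
        else:
            state = "indeterminate"
        rows.append(StateCall(s, r, state, None))
    for s, reasons in excluded.items():
        if s not in set(expr.samples):
            rows.append(StateCall(s, float("nan"), "excluded", ";".join(reasons)))
    return pd.DataFrame(
        {
            "sample": [c.sample for c in rows],
            "log2_ratio": [c.log2_ratio for c in rows],
            "state": [c.state for c in rows],
            "exclusion_reason": [c.exclusion_reason for c in rows],
        }
    ).set_index("sample")


def _pearson_permutation_p(
    x: np.ndarray, y: np.ndarray, rho: float, n_perm: int, rng: np.random.Generator
) -> float:
    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    perms = np.array([rng.permutation(len(ys)) for _ in range(n_perm)])
    rhos = (xs[None, :] * ys[perms]).mean(axis=1)
    return float((1 + np.sum(np.abs(rhos) >= abs(rho))) / (n_perm + 1))


def marker_correlations(
    expr: ExpressionMatrix,
    markers: MarkerSet = MarkerSet(),
    method: str = "t",
    n_perm: int = 9999,
    seed: int = 0,
) -> list[CorrelationResult]:
    """Pairwise Pearson correlations among the marker genes.

    Intended input: log2(x + 10)-transformed absolute read abundance.
    ``method='t'`` uses the classical t reference distribution with n - 2
    degrees of freedom; ``method='permutation'`` uses a seeded two-sided
    permutation test (B = n_perm). Constant genes yield an explicitly
    flagged undefined correlation.
    """
    markers.validate(expr.genes)
    n = expr.values.shape[1]
    if n < 3:
        raise DataError(f"need >= 3 samples for correlation, got {n}")
    rng = np.random.default_rng(seed)
    genes = list(dict.fromkeys(markers.all))
    out = []
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            x = expr.values.loc[a].to_numpy(dtype=float)
            y = expr.values.loc[b].to_numpy(dtype=float)
            if x.std() == 0 or y.std() == 0:
                out.append(CorrelationResult(a, b, float("nan"), float("nan"), n, True))
                continue
            if method == "permutation":
                rho = float(np.corrcoef(x, y)[0, 1])
                p = _pearson_permutation_p(x, y, rho, n_perm, rng)
            else:
                rho, p = stats.pearsonr(x, y)
                rho, p = float(rho), float(p)
            out.append(CorrelationResult(a, b, rho, p, n))
    return out


def correlations_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_a": [r.gene_a for r in results],
            "gene_b": [r.gene_b for r in results],
            "rho": [r.rho for r in results],
            "p_value": [r.p_value for r in results],
            "n": [r.n for r in results],
            "undefined": [r.undefined for r in results],
        }
    )


def write_state_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", float_format="%.10g")
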