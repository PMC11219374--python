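"""Univariate Mann-Whitney screening and hypergeometric over-representation analysis.

The rank-sum test runs on normalized, imputed, non-log intensities (ranks
are invariant to the monotone log transform anyway).  Over-representation
analysis asks, for each compound set of size K in a universe of N compounds,
how likely it is to see at least the observed overlap k in a query of n
mapped compounds: the upper-tail hypergeometric probability
p = sum_{i>=k} C(K,i) C(N-K,n-i) / C(N,n), with enrichment ratio =
observed/expected hits where expected = nK/N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (for the first sample) and two-sided p-value.

    U comes from rank sums with midranks for ties.  The p-value is exact
    (full enumeration over rank assignments) when n+m <= 20 and there are no
    ties, otherwise the normal approximation with tie correction and
    continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks for ties
    u1 = ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(u1), float(res.pvalue)


def univariate_screen(
    values: pd.DataFrame,
    groups: Sequence[str],
    analytes: Sequence[str] | None = None,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-analyte case-vs-control Mann-Whitney tests.

    ``values`` holds normalized, imputed intensities (not log-transformed).
    Returns U, raw two-sided p and the direction of the case median shift;
    Benjamini-Hochberg adjusted p-values are added when ``fdr`` is set.
    """
    groups = np.asarray(groups)
    case = groups == "case"
    control = groups == "control"
    if not case.any() or not control.any():
        raise DataError("need both case and control samples for univariate screening")
    cols = list(values.columns) if analytes is None else list(analytes)
    rows = []
    for analyte in cols:
        xv = values.loc[case, analyte].to_numpy()
        yv = values.loc[control, analyte].to_numpy()
        u, p = mann_whitney(xv, yv)
        rows.append(
            {
                "analyte": analyte,
                "U": u,
                "p_value": p,
                "direction": "up" if np.median(xv) > np.median(yv) else "down",
            }
        )
    out = pd.DataFrame(rows).set_index("analyte")
    if fdr:
        out["p_adjusted"] = benjamini_hochberg(out["p_value"].to_numpy())
    return out.sort_values("p_value")


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Step-up FDR adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adjusted[i] = running
    return adjusted


# ---------------------------------------------------------------------------
# compound-set libraries and ORA


@dataclass
class CompoundSetLibrary:
    """Named compound sets plus the universe they are tested against."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not self.sets:
            raise DataError("library contains no compound sets")
        for name, members in self.sets.items():
            if not members:
                raise DataError(f"compound set {name!r} is empty")
        union = frozenset().union(*self.sets.values())
        if self.universe is None:
            self.universe = union
        elif not union <= self.universe:
            raise DataError("explicit universe does not cover all set members")

    @property
    def n_universe(self) -> int:
        return len(self.universe)


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> CompoundSetLibrary:
    """Parse a GMT file: one tab-separated line per set (name, description, members...)."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise DataError(f"{Path(path).name}:{lineno}: GMT line needs name, description, members")
        name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
        if name in sets:
            raise DataError(f"{Path(path).name}:{lineno}: duplicate set name {name!r}")
        sets[name] = frozenset(members)
        descriptions[name] = desc
    return CompoundSetLibrary(
        sets=sets,
        descriptions=descriptions,
        universe=frozenset(universe) if universe is not None else None,
    )


def write_gmt(library: CompoundSetLibrary, path: str | Path) -> None:
    lines = [
        "\t".join([name, library.descriptions.get(name, "")] + sorted(members))
        for name, members in library.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class EnrichmentResult:
    """One compound set's over-representation outcome."""

    set_name: str
    hits: int
    expected: float
    enrichment_ratio: float | None  # None when expected is 0 (not-applicable)
    p_value: float
    query_size: int
    set_size: int


def hypergeometric_upper_tail(k: int, n_universe: int, set_size: int, query_size: int) -> float:
    """P(overlap >= k) for a query of ``query_size`` drawn without replacement
    from a universe containing ``set_size`` marked compounds."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, n_universe, set_size, query_size))


def ora(
    query: Iterable[str],
    library: CompoundSetLibrary,
) -> tuple[list[EnrichmentResult], int]:
    """Over-representation analysis of a compound query against every set.

    Query ids outside the universe are dropped (their count is returned);
    results are sorted by ascending p-value, ties by set name.
    """
    query = set(query)
    if not query:
        raise DataError("query compound set is empty")
    mapped = query & library.universe
    n_unmapped = len(query) - len(mapped)
    if not mapped:
        raise DataError("no query compound maps into the library universe")
    N, n = library.n_universe, len(mapped)
    results = []
    for name, members in library.sets.items():
        K = len(members)
        k = len(mapped & members)
        expected = n * K / N
        results.append(
            EnrichmentResult(
                set_name=name,
                hits=k,
                expected=expected,
                enrichment_ratio=(k / expected) if expected > 0 else None,
                p_value=hypergeometric_upper_tail(k, N, K, n),
                query_size=n,
                set_size=K,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results, n_unmapped


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set": r.set_name,
                "set_size": r.set_size,
                "hits": r.hits,
                "expected": r.expected,
                "enrichment_ratio": r.enrichment_ratio,
                "p_value": r.p_value,
            }
            for r in results
        ]
    )
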