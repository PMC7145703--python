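"""Matched-control comparison of convergence counts and the adaptive overlap.

Each echolocator pairwise comparison is matched with a nonecholocating
comparison at the same phylogenetic distance; the paired-sample t-test asks
whether parallel/convergent gene and site counts among echolocators exceed
those background levels. The adaptive overlap intersects positively selected
sites with parallel/convergent sites per gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

METRICS = ("parallel_genes", "parallel_sites", "convergent_genes", "convergent_sites")


@dataclass(frozen=True)
class PairedRow:
    """One matched pair of comparisons with its four count metrics per side."""

    echo_label: str
    control_label: str
    echo: dict[str, int]      # metric -> count for the echolocating comparison
    control: dict[str, int]   # metric -> count for the matched control

    def __post_init__(self):
        for side in (self.echo, self.control):
            missing = set(METRICS) - set(side)
            if missing:
                raise ValueError(f"row missing metrics: {sorted(missing)}")
            if any(v < 0 for v in side.values()):
                raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class PairedCountTable:
    rows: tuple[PairedRow, ...]

    def differences(self, metric: str) -> np.ndarray:
        if metric not in METRICS:
            raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
        return np.array([r.echo[metric] - r.control[metric] for r in self.rows], dtype=float)

    def column(self, metric: str, side: str) -> np.ndarray:
        vals = [getattr(r, side)[metric] for r in self.rows]
        return np.array(vals, dtype=float)


def _counts(pg: int, ps: int, cg: int, cs: int) -> dict[str, int]:
    return {"parallel_genes": pg, "parallel_sites": ps,
            "convergent_genes": cg, "convergent_sites": cs}


#: the study's published per-pair counts: seven matched rows of
#: parallel genes (sites) and convergent genes (sites), echolocating
#: comparison first, its equally phylogenetically distant control second
_TABLE1 = (
    ("CF vs. FM",                 _counts(154, 171, 0, 0),
     "CF vs. nonecholocating bat",    _counts(117, 124, 1, 1)),
    ("CF vs. click bat",          _counts(207, 248, 3, 3),
     "CF vs. nonecholocating bat",    _counts(117, 124, 1, 1)),
    ("FM vs. click bat",          _counts(177, 203, 6, 6),
     "FM vs. nonecholocating bat",    _counts(118, 122, 2, 2)),
    ("CF vs. toothed whale",      _counts(119, 129, 11, 11),
     "CF vs. nonecholocating whale",  _counts(84, 89, 5, 5)),
    ("FM vs. toothed whale",      _counts(94, 98, 2, 2),
     "FM vs. nonecholocating whale",  _counts(87, 92, 3, 3)),
    ("Click bat vs. toothed whale", _counts(96, 104, 11, 11),
     "Click bat vs. nonecholocating whale", _counts(90, 97, 3, 3)),
    ("Click bat vs. toothed whale", _counts(96, 104, 11, 11),
     "Nonecholocating bat vs. toothed whale", _counts(62, 65, 5, 5)),
)


def load_table1_fixture() -> PairedCountTable:
    """The packaged 7-row table of published per-pair convergence counts."""
    return PairedCountTable(rows=tuple(
        PairedRow(echo_label=el, control_label=cl, echo=e, control=c)
        for el, e, cl, c in _TABLE1
    ))


def paired_t_test(table: PairedCountTable, metric: str) -> tuple[float, int, float]:
    """Classical paired-sample t on (echolocating - control) differences.

    Returns (t, df, two-sided P); df = rows - 1. Zero-variance differences
    are a degenerate design and raise, rather than reporting P = 0.
    """
    diffs = table.differences(metric)
    if len(diffs) < 2:
        raise ValueError("need at least 2 paired rows")
    if np.allclose(diffs, diffs[0]):
        raise ValueError("degenerate pairs: zero-variance differences")
    echo = table.column(metric, "echo")
    ctrl = table.column(metric, "control")
    t, p = stats.ttest_rel(echo, ctrl)
    return float(t), len(diffs) - 1, float(p)


def t_test_report(table: PairedCountTable) -> list[dict]:
    """All four metrics, full precision internally, P rounded only here."""
    rows = []
    for metric in METRICS:
        t, df, p = paired_t_test(table, metric)
        rows.append({"metric": metric, "t": round(t, 6), "df": df,
                     "P": p, "P_2dp": round(p, 2)})
    return rows


@dataclass(frozen=True)
class OverlapRecord:
    gene_id: str
    site: int
    configurations: tuple[str, ...]  # foreground configs supporting selection
    pairs: tuple[str, ...]           # comparisons supporting the parallel call


def adaptive_overlap(
    selected_sites: Mapping[str, Mapping[str, Sequence[int]]],
    parallel_sites: Mapping[str, Mapping[str, Sequence[int]]],
) -> list[OverlapRecord]:
    """Sites that are simultaneously positively selected and parallel.

    ``selected_sites``: gene -> {foreground configuration -> site list};
    ``parallel_sites``: gene -> {pair label -> site list}. Coordinates are
    1-based original codon/amino-acid positions on both sides. The result is
    the exact site-level intersection, annotated with every configuration
    and pair supporting it.
    """
    records: list[OverlapRecord] = []
    for gene in sorted(set(selected_sites) & set(parallel_sites)):
        by_config = selected_sites[gene]
        by_pair = parallel_sites[gene]
        sel = {s for sites in by_config.values() for s in sites}
        par = {s for sites in by_pair.values() for s in sites}
        for site in sorted(sel & par):
            records.append(OverlapRecord(
                gene_id=gene, site=site,
                configurations=tuple(sorted(c for c, ss in by_config.items() if site in ss)),
                pairs=tuple(sorted(p for p, ss in by_pair.items() if site in ss)),
            ))
    return records


def table_rows(table: PairedCountTable) -> list[dict]:
    """TSV-ready rows mirroring the published table's column layout."""
    return [
        {
            "echo_comparison": r.echo_label,
            "echo_parallel_genes": r.echo["parallel_genes"],
            "echo_parallel_sites": r.echo["parallel_sites"],
            "echo_convergent_genes": r.echo["convergent_genes"],
            "echo_convergent_sites": r.echo["convergent_sites"],
            "control_comparison": r.control_label,
            "control_parallel_genes": r.control["parallel_genes"],
            "control_parallel_sites": r.control["parallel_sites"],
            "control_convergent_genes": r.control["convergent_genes"],
            "control_convergent_sites": r.control["convergent_sites"],
        }
        for r in table.rows
    ]
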