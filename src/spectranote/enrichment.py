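"""Functional-bin categorization, GO over-representation and set comparisons.

Over-representation uses the one-sided (upper tail) hypergeometric test:
given a background of ``bg_size`` proteins of which ``n_bg`` carry a term,
the p-value for a foreground of ``fg_size`` containing ``n_fg`` carriers is
P[X >= n_fg] under sampling without replacement.  Benjamini-Hochberg
adjustment across all tested terms controls the FDR; a term is enriched
when q <= the threshold (default 0.05).

Only directly annotated terms are tested — there is no GO-graph ancestor
propagation unless callers pre-propagate their annotation map.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import Annotation, UNASSIGNED_BIN

__all__ = ["categorize", "go_enrich", "venn", "unique_terms", "VennPartition"]


def categorize(
    accessions: Iterable[str], annotations: Mapping[str, Annotation]
) -> pd.DataFrame:
    """Assign each protein its top-level functional bin and tally the bins.

    The top-level bin is the first dot-component of the MapMan-style bin
    path; proteins absent from the annotation map fall into
    "not assigned.unknown" (top level "not assigned").  Returns a frame
    with columns bin, n, members sorted by descending count then bin name.
    """
    groups: dict[str, list[str]] = {}
    for acc in accessions:
        ann = annotations.get(acc)
        bin_path = ann.bin if ann is not None else UNASSIGNED_BIN
        top = bin_path.split(".", 1)[0]
        groups.setdefault(top, []).append(acc)
    rows = [
        {"bin": b, "n": len(members), "members": ";".join(sorted(members))}
        for b, members in groups.items()
    ]
    df = pd.DataFrame(rows, columns=["bin", "n", "members"])
    return df.sort_values(["n", "bin"], ascending=[False, True], kind="stable").reset_index(
        drop=True
    )


def go_enrich(
    foreground: Iterable[str],
    background: Iterable[str],
    annotations: Mapping[str, Annotation],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of GO terms with BH control.

    Every term annotated to at least one background protein is tested.
    Returns a frame sorted by (q_value, p_value, term) with columns term,
    n_fg, n_bg, fg_size, bg_size, p_value, q_value, enriched.
    """
    fg = set(foreground)
    bg = set(background)
    if not fg <= bg:
        raise ValueError(
            f"foreground not a subset of background (e.g. {sorted(fg - bg)[:3]})"
        )
    term_bg: dict[str, int] = {}
    term_fg: dict[str, int] = {}
    for acc in bg:
        ann = annotations.get(acc)
        if ann is None:
            continue
        in_fg = acc in fg
        for t in ann.go_terms:
            term_bg[t] = term_bg.get(t, 0) + 1
            if in_fg:
                term_fg[t] = term_fg.get(t, 0) + 1
    if not term_bg:
        return pd.DataFrame(
            columns=["term", "n_fg", "n_bg", "fg_size", "bg_size", "p_value", "q_value", "enriched"]
        )
    terms = sorted(term_bg)
    n_bg = np.array([term_bg[t] for t in terms])
    n_fg = np.array([term_fg.get(t, 0) for t in terms])
    M, N = len(bg), len(fg)
    p = stats.hypergeom.sf(n_fg - 1, M, n_bg, N)
    p = np.clip(p, 0.0, 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    df = pd.DataFrame(
        {
            "term": terms,
            "n_fg": n_fg,
            "n_bg": n_bg,
            "fg_size": N,
            "bg_size": M,
            "p_value": p,
            "q_value": q,
            "enriched": q <= fdr,
        }
    )
    return df.sort_values(["q_value", "p_value", "term"], kind="stable").reset_index(
        drop=True
    )


@dataclasses.dataclass
class VennPartition:
    """Exact partition of 2..n sets into their 2^n - 1 exclusive regions.

    ``regions`` maps a tuple of member labels (the sets an element belongs
    to, in input label order) to the sorted element list of that exclusive
    region.  Region sizes sum to the union size by construction.
    """

    labels: list[str]
    regions: dict[tuple[str, ...], list[str]]

    @property
    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def size(self, *labels: str) -> int:
        return len(self.regions.get(tuple(labels), []))

    def percent(self, *labels: str) -> int:
        """Region size as an integer percentage of the union."""
        if self.union_size == 0:
            raise ValueError("empty union")
        return int(np.floor(100 * self.size(*labels) / self.union_size + 0.5))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "region": "&".join(key),
                "n": len(members),
                "pct_of_union": self.percent(*key),
                "members": ";".join(members),
            }
            for key, members in sorted(
                self.regions.items(), key=lambda kv: (-len(kv[0]), kv[0])
            )
        ]
        return pd.DataFrame(rows, columns=["region", "n", "pct_of_union", "members"])


def venn(sets: Mapping[str, Iterable[str]], allow_many: bool = False) -> VennPartition:
    """Partition labelled sets into exclusive membership regions.

    Limited to 2-4 sets (the plottable range) unless ``allow_many``.
    """
    labels = list(sets)
    if len(labels) < 2:
        raise ValueError("venn needs >= 2 sets")
    if len(labels) > 4 and not allow_many:
        raise ValueError("more than 4 sets: pass allow_many=True to compute anyway")
    materialized = {lab: set(sets[lab]) for lab in labels}
    universe = sorted(set().union(*materialized.values()))
    regions: dict[tuple[str, ...], list[str]] = {}
    for el in universe:
        key = tuple(lab for lab in labels if el in materialized[lab])
        regions.setdefault(key, []).append(el)
    return VennPartition(labels=labels, regions=regions)


def unique_terms(
    comparison_results: Mapping[str, Iterable[str]]
) -> tuple[dict[str, set[str]], VennPartition]:
    """Terms enriched in exactly one comparison, plus the full partition.

    Input maps each comparison label to its enriched term set; returns
    (per-comparison unique sets, VennPartition of the term sets).
    """
    labels = list(comparison_results)
    if len(labels) < 2:
        raise ValueError("needs >= 2 comparisons")
    part = venn(comparison_results, allow_many=True)
    uniq = {
        lab: set(part.regions.get((lab,), []))
        for lab in labels
    }
    return uniq, part
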