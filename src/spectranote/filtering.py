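"""Replicate-presence filtering and per-treatment detection sets.

The dataset filter keeps a protein only if some treatment detected it in
every biological replicate ("max count" equal to the replicate number).
This guards against one-off identifications: a protein seen once in one
replicate carries no quantitative signal, while full presence in at least
one treatment means the protein is reliably observable somewhere in the
design.  Detection is a property of the spectra, so the filter runs on PSM
counts, not on NSAF values (their zeros coincide anyway).
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .io import CountMatrix

__all__ = ["FilterConfig", "PresenceResult", "presence_filter", "detection_sets"]


@dataclasses.dataclass(frozen=True)
class FilterConfig:
    """Presence-filter setting.

    ``min_replicates`` is either the string ``"all"`` (a treatment qualifies
    only when every one of its replicates detects the protein — the study's
    "max count 3" rule for triplicates) or an explicit integer threshold.
    """

    min_replicates: int | str = "all"

    def threshold_for(self, n_replicates: int) -> int:
        if self.min_replicates == "all":
            return n_replicates
        k = int(self.min_replicates)
        if k < 1:
            raise ValueError("min_replicates must be >= 1")
        if k > n_replicates:
            raise ValueError(
                f"min_replicates {k} exceeds treatment replicate count {n_replicates}"
            )
        return k


@dataclasses.dataclass
class PresenceResult:
    """Outcome of the presence filter.

    ``retained`` preserves the input protein order; ``qualifying`` is a
    boolean proteins x treatments frame marking which treatments satisfied
    the replicate threshold for each protein.
    """

    retained: list[str]
    qualifying: pd.DataFrame

    @property
    def retained_set(self) -> set[str]:
        return set(self.retained)


def presence_filter(counts: CountMatrix, cfg: FilterConfig | None = None) -> PresenceResult:
    """Keep proteins detected in >= threshold replicates of >= 1 treatment."""
    cfg = cfg or FilterConfig()
    det = counts.detected()
    qual = {}
    for t in counts.treatments:
        samples = counts.samples_of(t)
        thr = cfg.threshold_for(len(samples))
        qual[t] = det[samples].sum(axis=1) >= thr
    qualifying = pd.DataFrame(qual)
    keep = qualifying.any(axis=1)
    return PresenceResult(retained=list(counts.counts.index[keep]), qualifying=qualifying)


def detection_sets(counts: CountMatrix) -> dict[str, set[str]]:
    """Map each treatment to the proteins detected in >= 1 of its replicates."""
    det = counts.detected()
    out: dict[str, set[str]] = {}
    for t in counts.treatments:
        mask = det[counts.samples_of(t)].any(axis=1)
        out[t] = set(counts.counts.index[mask])
    return out
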