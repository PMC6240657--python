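"""Synthetic spectral-count data with known ground truth.

The generator emulates the statistical structure a spectral-counting
experiment imposes on its counts:

* protein lengths are log-uniform over a plausible amino-acid range;
* each protein has a baseline relative abundance drawn log-normally (a
  long-tailed abundance distribution, as in real proteomes);
* treatment effects multiply the abundance of designated proteins in
  designated treatments;
* each replicate draws its PSM counts multinomially with a fixed spectral
  budget (``total_psm_per_sample`` trials), with sampling weights
  proportional to abundance x length x log-normal replicate jitter.  The
  length factor matters: NSAF divides by length, so simulating it makes
  the length correction a real operation rather than a no-op;
* detection dropout is abundance-dependent: a protein's probability of
  being observed at all in a sample follows a logistic curve in the log of
  its expected PSM count, which produces the all-replicate absences the
  differential rule's absence branch exists for.

``simulate`` returns the counts together with a :class:`SyntheticTruth`
holding the true compositions, effect multipliers and detection masks, so
recovery tests can score the pipeline against what was planted.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import Annotation, CountMatrix

__all__ = ["SimConfig", "SyntheticTruth", "simulate", "pollen_fixture", "TREATMENTS"]

#: The four-condition pollen design: control, heat stress, ethephon
#: pre-treatment + control, ethephon pre-treatment + heat stress.
TREATMENTS = ("P-C", "P-HS", "P-E-C", "P-E-HS")


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    ``effect_log2fold`` and ``affected_treatments`` describe the default
    effect model: each affected protein's abundance is multiplied by
    2**(+-effect_log2fold) (sign drawn at random per protein) in every
    affected treatment.  ``dropout_midpoint`` is the expected per-sample
    PSM count at which detection probability is 50%; ``dropout_slope``
    scales the logistic steepness in log-count units.  The default slope
    makes the logistic track 1 - exp(-E[count]) — the missingness pure
    counting statistics would impose — for expected counts above the
    midpoint, so detection failure supplements rather than dwarfs the
    Poisson-level noise at moderate abundance.
    """

    n_proteins: int = 1000
    treatments: tuple[str, ...] = TREATMENTS
    n_replicates: int = 3
    length_range: tuple[int, int] = (100, 1200)
    total_psm_per_sample: int = 20000
    baseline_sigma: float = 1.2
    replicate_sigma: float = 0.25
    de_fraction: float = 0.0
    effect_log2fold: float = 2.0
    affected_treatments: tuple[str, ...] = ("P-HS",)
    dropout: bool = True
    dropout_midpoint: float = 1.0
    dropout_slope: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.n_proteins < 1 or self.n_replicates < 1:
            raise ValueError("n_proteins and n_replicates must be >= 1")
        if self.total_psm_per_sample < 1:
            raise ValueError("total_psm_per_sample must be >= 1")
        unknown = set(self.affected_treatments) - set(self.treatments)
        if unknown:
            raise ValueError(f"affected treatments not in design: {sorted(unknown)}")


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth emitted alongside simulated counts.

    ``abundance`` holds each treatment's true relative-abundance
    composition (columns sum to 1); ``multipliers`` the planted effect
    factors (1 = unaffected); ``detection`` the realized per-sample
    detection mask.
    """

    abundance: pd.DataFrame     # proteins x treatments, columns sum to 1
    multipliers: pd.DataFrame   # proteins x treatments
    detection: pd.DataFrame     # proteins x samples, bool

    def true_fold(self, treat_a: str, treat_b: str) -> pd.Series:
        """Planted signed fold of B vs A from the effect multipliers."""
        r = self.multipliers[treat_b] / self.multipliers[treat_a]
        return pd.Series(
            np.where(r >= 1, r, -1 / r), index=self.multipliers.index
        )

    def de_labels(self, treat_a: str, treat_b: str) -> pd.Series:
        """True iff the planted multipliers differ between the pair."""
        return self.multipliers[treat_a] != self.multipliers[treat_b]


def _design_frame(treatments: tuple[str, ...], n_replicates: int) -> pd.DataFrame:
    rows = [
        {"sample_id": f"{t}_r{r}", "treatment": t, "replicate": r}
        for t in treatments
        for r in range(1, n_replicates + 1)
    ]
    return pd.DataFrame(rows)


def simulate(
    cfg: SimConfig,
    multipliers: pd.DataFrame | None = None,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw one synthetic experiment.

    ``multipliers`` (proteins x treatments effect factors) overrides the
    config's random effect model; this is how structured fixtures plant
    bin-specific shifts.  Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_proteins
    accs = [f"SYN{i:05d}" for i in range(n)]

    lo, hi = cfg.length_range
    lengths = np.rint(np.exp(rng.uniform(np.log(lo), np.log(hi), n))).astype(int)
    lengths = np.clip(lengths, 1, None)

    baseline = rng.lognormal(mean=0.0, sigma=cfg.baseline_sigma, size=n)

    if multipliers is None:
        mult = pd.DataFrame(1.0, index=accs, columns=list(cfg.treatments))
        n_de = int(round(cfg.de_fraction * n))
        if n_de:
            idx = rng.choice(n, size=n_de, replace=False)
            signs = rng.choice([-1.0, 1.0], size=n_de)
            factor = 2.0 ** (signs * cfg.effect_log2fold)
            for t in cfg.affected_treatments:
                mult.iloc[idx, mult.columns.get_loc(t)] = factor
    else:
        mult = multipliers.copy()
        mult.index = accs[: len(mult)]
        if list(mult.columns) != list(cfg.treatments) or len(mult) != n:
            raise ValueError("multipliers must be n_proteins x treatments")

    abund = baseline[:, None] * mult.to_numpy()  # proteins x treatments
    design = _design_frame(cfg.treatments, cfg.n_replicates)

    counts = np.zeros((n, len(design)), dtype=np.int64)
    detect = np.zeros((n, len(design)), dtype=bool)
    for j, row in enumerate(design.itertuples(index=False)):
        t_idx = list(cfg.treatments).index(row.treatment)
        jitter = rng.lognormal(mean=0.0, sigma=cfg.replicate_sigma, size=n)
        w = abund[:, t_idx] * lengths * jitter
        expected = cfg.total_psm_per_sample * w / w.sum()
        if cfg.dropout:
            z = cfg.dropout_slope * (
                np.log(expected) - np.log(cfg.dropout_midpoint)
            )
            p_det = 1.0 / (1.0 + np.exp(-z))
        else:
            p_det = np.ones(n)
        mask = rng.random(n) < p_det
        if not mask.any():
            raise RuntimeError(f"all proteins dropped in sample {row.sample_id}")
        w_obs = np.where(mask, w, 0.0)
        counts[:, j] = rng.multinomial(cfg.total_psm_per_sample, w_obs / w_obs.sum())
        detect[:, j] = mask

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=accs, columns=list(design["sample_id"])),
        lengths=pd.Series(lengths, index=accs),
        design=design,
    )
    truth = SyntheticTruth(
        abundance=pd.DataFrame(
            abund / abund.sum(axis=0), index=accs, columns=list(cfg.treatments)
        ),
        multipliers=mult,
        detection=pd.DataFrame(detect, index=accs, columns=list(design["sample_id"])),
    )
    return cm, truth


# ---------------------------------------------------------------------------
# the canonical pollen fixture
# ---------------------------------------------------------------------------

# bin -> (fraction of proteins, bin-linked toy GO term or None)
_FIXTURE_BINS: list[tuple[str, float, str | None]] = [
    ("protein.synthesis.ribosomal protein", 0.15, "GO:0006412"),
    ("TCA/org. transformation.TCA", 0.06, "GO:0006099"),
    ("stress.abiotic.heat", 0.04, "GO:0009408"),
    ("redox.ascorbate and glutathione", 0.05, "GO:0045454"),
    ("RNA.regulation of transcription", 0.08, "GO:0003723"),
    ("signalling.G-proteins", 0.06, "GO:0007165"),
    ("transport.p- and v-ATPases", 0.07, "GO:0006810"),
    ("misc.enzyme families", 0.10, "GO:0003824"),
    ("development.unspecified", 0.05, None),
    ("cell.organisation", 0.06, None),
]

# bin -> (multiplier in P-HS, multiplier in P-E-HS): heat stress depresses
# the translation and TCA machinery and induces the stress bin; ethephon
# pre-treatment attenuates both shifts toward control.
_FIXTURE_EFFECTS: dict[str, tuple[float, float]] = {
    "protein.synthesis.ribosomal protein": (0.25, 0.70),
    "TCA/org. transformation.TCA": (0.30, 0.75),
    "stress.abiotic.heat": (4.00, 1.80),
}


def pollen_fixture(
    seed: int = 0, n_proteins: int = 1000, total_psm_per_sample: int = 20000
) -> tuple[CountMatrix, SyntheticTruth, dict[str, Annotation]]:
    """Canonical 4-treatment x 3-replicate pollen-style dataset.

    Roughly 72% of proteins carry a functional bin (the rest are
    unannotated and default downstream to "not assigned.unknown").  Heat
    stress (P-HS) down-shifts the translation and TCA bins four- and
    three-fold and up-shifts a small heat-stress bin four-fold; ethephon
    pre-treatment before heat stress (P-E-HS) attenuates every shift
    toward the control level.  Bin-linked toy GO terms make the designed
    shifts recoverable by enrichment.  Returns (counts, truth, annotations).
    """
    cfg = SimConfig(
        n_proteins=n_proteins,
        total_psm_per_sample=total_psm_per_sample,
        seed=seed,
    )
    rng = np.random.default_rng(seed + 104729)  # annotation layout stream
    accs = [f"SYN{i:05d}" for i in range(n_proteins)]

    order = rng.permutation(n_proteins)
    annotations: dict[str, Annotation] = {}
    bin_of = {}
    pos = 0
    for bin_path, frac, go in _FIXTURE_BINS:
        k = int(round(frac * n_proteins))
        for i in order[pos : pos + k]:
            acc = accs[i]
            terms = set()
            if go is not None and rng.random() < 0.9:
                terms.add(go)
            if rng.random() < 0.3:
                terms.add("GO:0008150")  # broad term shared across bins
            annotations[acc] = Annotation(bin=bin_path, go_terms=frozenset(terms))
            bin_of[acc] = bin_path
        pos += k
    # remaining ~28% stay unannotated

    mult = pd.DataFrame(1.0, index=accs, columns=list(TREATMENTS))
    for bin_path, (f_hs, f_ehs) in _FIXTURE_EFFECTS.items():
        members = [a for a, b in bin_of.items() if b == bin_path]
        mult.loc[members, "P-HS"] = f_hs
        mult.loc[members, "P-E-HS"] = f_ehs

    cm, truth = simulate(cfg, multipliers=mult)
    return cm, truth, annotations
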