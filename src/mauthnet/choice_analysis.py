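"""Decision surfaces of the escape circuit.

Turns raw stimulus-grid sweeps into choice maps (which M-cell fires where,
and when), compares circuit variants by the areas of their outcome regions,
and quantifies the two behavioral predictions of the model: latency
shortening after feedforward-inhibition removal, and the contralateral
laterality bias after one-sided removal.

Outcome classes follow the figure convention: LEFT_ONLY (only the left
M-cell fires; the fish turns right), RIGHT_ONLY, BOTH, NEITHER.  A
condition where both cells fire in the observation window is BOTH
regardless of their relative timing; latencies are measured from afferent
drive onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .circuit import AblationSpec, CircuitSpec, build_circuit
from .errors import ConfigurationError
from .protocols import SweepResult, run_unilateral

__all__ = [
    "NEITHER", "LEFT_ONLY", "RIGHT_ONLY", "BOTH", "OUTCOME_LABELS",
    "ChoiceMap", "classify_outcomes", "VariantComparison", "compare_variants",
    "LatencyCurve", "latency_vs_strength", "BiasSummary",
    "bias_after_ablation", "summarize_bias",
]

NEITHER, LEFT_ONLY, RIGHT_ONLY, BOTH = 0, 1, 2, 3
OUTCOME_LABELS = {NEITHER: "NEITHER", LEFT_ONLY: "LEFT_ONLY",
                  RIGHT_ONLY: "RIGHT_ONLY", BOTH: "BOTH"}
_LABEL_CODES = {v: k for k, v in OUTCOME_LABELS.items()}


@dataclass
class ChoiceMap:
    """Outcome class and M-cell latencies over a (left, right) stimulus grid.

    ``outcome[i, j]`` is the class at left strength ``strengths_left[i]`` and
    right strength ``strengths_right[j]``; ``lat_left``/``lat_right`` are the
    first-spike latencies in ms from drive onset (NaN where silent).
    """

    strengths_left: np.ndarray
    strengths_right: np.ndarray
    outcome: np.ndarray  # int, codes above
    lat_left: np.ndarray
    lat_right: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        both = ~np.isnan(self.lat_left) & ~np.isnan(self.lat_right)
        neither = np.isnan(self.lat_left) & np.isnan(self.lat_right)
        if not ((self.outcome == BOTH) == both).all():
            raise ValueError("outcome BOTH must coincide with both latencies present")
        if not ((self.outcome == NEITHER) == neither).all():
            raise ValueError("outcome NEITHER must coincide with no latencies")

    @property
    def n_cells(self) -> int:
        return self.outcome.size

    def area(self, code: int) -> float:
        """Fraction of grid cells in the given outcome class."""
        return float((self.outcome == code).mean())

    def areas(self) -> dict[str, float]:
        return {label: self.area(code) for code, label in OUTCOME_LABELS.items()}

    def mirrored(self) -> "ChoiceMap":
        """The map of the left/right-swapped experiment."""
        swap = {LEFT_ONLY: RIGHT_ONLY, RIGHT_ONLY: LEFT_ONLY}
        out = np.vectorize(lambda c: swap.get(c, c))(self.outcome.T).astype(
            self.outcome.dtype)
        return ChoiceMap(
            strengths_left=self.strengths_right.copy(),
            strengths_right=self.strengths_left.copy(),
            outcome=out, lat_left=self.lat_right.T.copy(),
            lat_right=self.lat_left.T.copy(), metadata=dict(self.metadata))

    def equals(self, other: "ChoiceMap") -> bool:
        return (
            np.array_equal(self.strengths_left, other.strengths_left)
            and np.array_equal(self.strengths_right, other.strengths_right)
            and np.array_equal(self.outcome, other.outcome)
            and np.array_equal(self.lat_left, other.lat_left, equal_nan=True)
            and np.array_equal(self.lat_right, other.lat_right, equal_nan=True))

    # -- IO ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        iL, iR = np.meshgrid(np.arange(len(self.strengths_left)),
                             np.arange(len(self.strengths_right)),
                             indexing="ij")
        return pd.DataFrame({
            "sL": self.strengths_left[iL.ravel()],
            "sR": self.strengths_right[iR.ravel()],
            "outcome": [OUTCOME_LABELS[c] for c in self.outcome.ravel()],
            "latency_left_ms": self.lat_left.ravel(),
            "latency_right_ms": self.lat_right.ravel(),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "ChoiceMap":
        df = pd.read_csv(path)
        sL = np.unique(df["sL"].to_numpy())
        sR = np.unique(df["sR"].to_numpy())
        shape = (len(sL), len(sR))
        iL = np.searchsorted(sL, df["sL"].to_numpy())
        iR = np.searchsorted(sR, df["sR"].to_numpy())
        outcome = np.zeros(shape, dtype=np.int8)
        latL = np.full(shape, np.nan)
        latR = np.full(shape, np.nan)
        outcome[iL, iR] = [_LABEL_CODES[o] for o in df["outcome"]]
        latL[iL, iR] = df["latency_left_ms"]
        latR[iL, iR] = df["latency_right_ms"]
        return ChoiceMap(sL, sR, outcome, latL, latR)

    def plot(self, ax=None, show_latency: bool = False):
        """Render the map in the red/blue/white figure convention."""
        from matplotlib.colors import ListedColormap

        if ax is None:
            import matplotlib.pyplot as plt

            _, ax = plt.subplots()
        if show_latency:
            lat = np.nanmin(np.stack([self.lat_left, self.lat_right]), axis=0)
            img = ax.pcolormesh(self.strengths_left, self.strengths_right,
                                lat.T, shading="nearest", cmap="viridis")
            ax.figure.colorbar(img, ax=ax, label="latency (ms)")
        else:
            cmap = ListedColormap(["0.6", "red", "blue", "white"])
            ax.pcolormesh(self.strengths_left, self.strengths_right,
                          self.outcome.T, shading="nearest", cmap=cmap,
                          vmin=-0.5, vmax=3.5)
        ax.set_xlabel("left stimulus strength")
        ax.set_ylabel("right stimulus strength")
        return ax


def classify_outcomes(sweep: SweepResult) -> ChoiceMap:
    """Deterministic outcome classification of a stimulus-grid sweep.

    Latencies are measured from drive onset; when an M-cell fires more than
    once only its first spike is used (noted in metadata).
    """
    onset = sweep.grid.onset
    latL = sweep.m_first_left - onset
    latR = sweep.m_first_right - onset
    hasL = ~np.isnan(latL)
    hasR = ~np.isnan(latR)
    outcome = np.full(latL.shape, NEITHER, dtype=np.int8)
    outcome[hasL & ~hasR] = LEFT_ONLY
    outcome[hasR & ~hasL] = RIGHT_ONLY
    outcome[hasL & hasR] = BOTH
    multi = int((sweep.batch.n_spikes[("M", "left")] > 1).sum()
                + (sweep.batch.n_spikes[("M", "right")] > 1).sum())
    return ChoiceMap(
        strengths_left=np.asarray(sweep.grid.strengths_left, dtype=float),
        strengths_right=np.asarray(sweep.grid.strengths_right, dtype=float),
        outcome=outcome, lat_left=latL, lat_right=latR,
        metadata={**sweep.metadata,
                  "onset_ms": onset,
                  "n_multi_spike_trials": multi})


# ---------------------------------------------------------------------------
# variant comparison
# ---------------------------------------------------------------------------


@dataclass
class VariantComparison:
    """Outcome-region areas per circuit variant, plus the key orderings."""

    areas: pd.DataFrame  # index: variant, columns: outcome labels
    orderings: dict[str, bool]


def compare_variants(maps: Mapping[str, ChoiceMap]) -> VariantComparison:
    """Compare outcome-region areas across circuit variants.

    All maps must share a stimulus grid.  When the relevant variants are
    present, reports whether mutual FF inhibition shrinks the biased
    circuit's no-response region, and whether the ipsi-only circuit has a
    larger simultaneous-response region than the full circuit.
    """
    maps = dict(maps)
    if not maps:
        raise ConfigurationError("no maps given")
    ref = next(iter(maps.values()))
    for name, m in maps.items():
        if (not np.array_equal(m.strengths_left, ref.strengths_left)
                or not np.array_equal(m.strengths_right, ref.strengths_right)):
            raise ConfigurationError(f"map {name!r} uses a different grid")
    rows = {name: m.areas() for name, m in maps.items()}
    areas = pd.DataFrame(rows).T
    orderings: dict[str, bool] = {}
    if {"biased_bilateral", "biased_bilateral_mutual"} <= set(maps):
        orderings["mutual_inhibition_shrinks_neither_region"] = bool(
            areas.loc["biased_bilateral", "NEITHER"]
            > areas.loc["biased_bilateral_mutual", "NEITHER"])
    if {"ipsi_only", "biased_bilateral_mutual"} <= set(maps):
        orderings["ipsi_only_has_larger_both_region"] = bool(
            areas.loc["ipsi_only", "BOTH"]
            > areas.loc["biased_bilateral_mutual", "BOTH"])
    return VariantComparison(areas=areas, orderings=orderings)


# ---------------------------------------------------------------------------
# ablation predictions
# ---------------------------------------------------------------------------

_CONDITIONS = ("control", "half_ablated", "all_ablated")


@dataclass
class LatencyCurve:
    """M-cell latency vs unilateral stimulus strength per ablation condition.

    ``latencies[condition]`` is in ms from drive onset (NaN below response
    threshold); conditions are control / half_ablated / all_ablated of the
    FF pool on the stimulated side.
    """

    strengths: np.ndarray
    side: str
    latencies: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def ordering_holds(self) -> bool:
        """all_ablated <= half_ablated <= control wherever all respond."""
        ctl = self.latencies["control"]
        half = self.latencies["half_ablated"]
        full = self.latencies["all_ablated"]
        ok = ~(np.isnan(ctl) | np.isnan(half) | np.isnan(full))
        if not ok.any():
            return False
        return bool(np.all(full[ok] <= half[ok] + 1e-9)
                    and np.all(half[ok] <= ctl[ok] + 1e-9))

    def strictly_ordered_somewhere(self) -> bool:
        ctl = self.latencies["control"]
        full = self.latencies["all_ablated"]
        ok = ~(np.isnan(ctl) | np.isnan(full))
        return bool(np.any(full[ok] < ctl[ok]))


def latency_vs_strength(strengths, side: str = "left", *,
                        circuit: CircuitSpec | None = None,
                        t_end: float = 55.0) -> LatencyCurve:
    """Latency-vs-strength curves for control and FF-ablated circuits.

    The FF pool on the stimulated side is left intact (control), half
    removed, or fully removed; stimulation is unilateral on that side.
    """
    base = circuit if circuit is not None else build_circuit()
    if base.ablations:
        raise ConfigurationError("pass an unablated circuit as the control")
    curves: dict[str, np.ndarray] = {}
    for cond in _CONDITIONS:
        if cond == "control":
            circ = base
        else:
            frac = "half" if cond == "half_ablated" else "all"
            circ = build_circuit(
                base.variant,
                ablations=[AblationSpec("FF_pool", side, frac)],
                config=base.config)
        res = run_unilateral(circ, strengths, side, t_end=t_end)
        curves[cond] = res["latency_ms"]
    return LatencyCurve(
        strengths=np.asarray(strengths, dtype=float), side=side,
        latencies=curves, metadata={"variant": base.variant.value})


@dataclass
class BiasSummary:
    """Outcome-class composition of one choice map, plus initiation shares.

    ``initiated`` gives, over responding conditions only, the fraction in
    which each M-cell fired first (BOTH-class ties split evenly); the two
    fractions sum to 1 whenever any condition responds.
    """

    counts: dict[str, int]
    fractions: dict[str, float]
    initiated: dict[str, float]
    n_responding: int

    @staticmethod
    def of(cmap: ChoiceMap) -> "BiasSummary":
        counts = {label: int((cmap.outcome == code).sum())
                  for code, label in OUTCOME_LABELS.items()}
        fractions = {label: c / cmap.n_cells for label, c in counts.items()}
        responding = cmap.outcome != NEITHER
        n_resp = int(responding.sum())
        init = {"left": 0.0, "right": 0.0}
        if n_resp:
            latL, latR = cmap.lat_left, cmap.lat_right
            left_first = responding & (np.nan_to_num(latL, nan=np.inf)
                                       < np.nan_to_num(latR, nan=np.inf))
            right_first = responding & (np.nan_to_num(latR, nan=np.inf)
                                        < np.nan_to_num(latL, nan=np.inf))
            tie = responding & ~left_first & ~right_first
            init["left"] = float((left_first.sum() + 0.5 * tie.sum()) / n_resp)
            init["right"] = float((right_first.sum() + 0.5 * tie.sum()) / n_resp)
        return BiasSummary(counts=counts, fractions=fractions,
                           initiated=init, n_responding=n_resp)


def summarize_bias(cmap: ChoiceMap) -> BiasSummary:
    return BiasSummary.of(cmap)


def bias_after_ablation(map_control: ChoiceMap, map_ablated: ChoiceMap,
                        ablated_side: str) -> tuple[BiasSummary, BiasSummary]:
    """Bias summaries before/after unilateral FF removal.

    After removing the FF pool on ``ablated_side``, the opposite M-cell is
    released from its strongest (crossed) inhibition, so the area of
    opposite-side-only outcomes grows; compare the two summaries.
    """
    if ablated_side not in ("left", "right"):
        raise ConfigurationError(f"unknown side {ablated_side!r}")
    return BiasSummary.of(map_control), BiasSummary.of(map_ablated)
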