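"""Amplification dynamics of a TE lineage from its copy tree.

Every internal node of a clock-like copy tree is one duplicative
transposition event; plotting the cumulative number of events against node
age (in divergence units from the present) gives the lineage-through-time
(LTT) curve of the amplification.  Four qualitative regimes are
distinguished by comparing the normalised curve with the diagonal expected
under a constant transposition rate:

* ``L`` (linear): constant events per unit time — the curve tracks the
  diagonal and the median event sits mid-span;
* ``E`` (exponential): constant per-copy rate — events pile up toward the
  present, the curve stays below the diagonal, the median shifts recent;
* ``C`` (concave): high initial rate that decays — the mirror image, with
  the median shifted ancient;
* ``S`` (S-shaped): slow start, burst, slow-down — an inflected curve with
  a centred median but large deviation from the diagonal.

A lineage with an event at (or within ``recent_epsilon`` of) the present is
called still active.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib
import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree

from .seqcore import SequenceRecord

# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class CopyTree:
    leaf_ids: list[str]
    linkage_matrix: np.ndarray          # scipy hierarchical-clustering format
    node_ages: np.ndarray               # one age per internal node, JC units

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def newick(self) -> str:
        root = to_tree(self.linkage_matrix)

        def fmt(node, parent_height: float) -> str:
            height = 0.0 if node.is_leaf() else node.dist
            bl = max(parent_height - height, 0.0) / 2.0  # heights are distances
            if node.is_leaf():
                return f"{self.leaf_ids[node.id]}:{bl:.6f}"
            return (f"({fmt(node.left, node.dist)},{fmt(node.right, node.dist)})"
                    f":{bl:.6f}")

        inner = f"({fmt(root.left, root.dist)},{fmt(root.right, root.dist)})"
        return inner + ";"


@dataclass
class LTTCurve:
    event_ages: np.ndarray              # sorted descending (oldest first)
    cumulative: np.ndarray              # 1..total_events

    @property
    def total_events(self) -> int:
        return len(self.event_ages)

    @classmethod
    def from_event_ages(cls, ages) -> "LTTCurve":
        ages = np.sort(np.asarray(ages, dtype=float))[::-1]
        if len(ages) == 0:
            raise ValueError("need at least one event")
        return cls(ages, np.arange(1, len(ages) + 1))


@dataclass
class DynamicsSummary:
    time_span: tuple[float, float]      # (oldest event age, youngest)
    median_event_age: float
    active_now: bool
    shape: str


# ---------------------------------------------------------------------------
# Copy tree
# ---------------------------------------------------------------------------


def jc_distance(a: str, b: str) -> float:
    """Jukes-Cantor-corrected distance from a global pairwise alignment."""
    res = edlib.align(a.upper(), b.upper(), mode="NW", task="distance")
    p = res["editDistance"] / max(len(a), len(b))
    if p >= 0.70:
        return 3.0   # effectively saturated
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def build_copy_tree(copies: list[SequenceRecord], max_copies: int = 500,
                    rng_seed: int = 7) -> CopyTree:
    """UPGMA tree on Jukes-Cantor distances; node age = half the corrected
    distance at each merge (a clock-like reading of divergence as time).
    Lineages larger than ``max_copies`` are subsampled deterministically."""
    if len(copies) < 3:
        raise ValueError("dynamics needs at least 3 copies")
    if len(copies) > max_copies:
        rng = np.random.default_rng(rng_seed)
        idx = np.sort(rng.choice(len(copies), size=max_copies, replace=False))
        copies = [copies[i] for i in idx]
    n = len(copies)
    condensed = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            condensed[k] = jc_distance(copies[i].residues, copies[j].residues)
            k += 1
    Z = linkage(condensed, method="average")
    return CopyTree([c.id for c in copies], Z, Z[:, 2] / 2.0)


def ltt_curve(tree: CopyTree) -> LTTCurve:
    """One duplicative transposition event per internal node."""
    return LTTCurve.from_event_ages(tree.node_ages)


# ---------------------------------------------------------------------------
# Summaries and shape classification
# ---------------------------------------------------------------------------


def summarize(ltt: LTTCurve, recent_epsilon: float = 0.005) -> DynamicsSummary:
    ages = ltt.event_ages
    total = ltt.total_events
    half_idx = int(np.searchsorted(ltt.cumulative, total / 2.0, side="left"))
    median_age = float(ages[min(half_idx, total - 1)])
    return DynamicsSummary(
        time_span=(float(ages[0]), float(ages[-1])),
        median_event_age=median_age,
        active_now=bool(ages[-1] <= recent_epsilon),
        shape=classify_shape(ltt))


def classify_shape(ltt: LTTCurve, delta_l: float | None = None,
                   f_low: float = 0.35, f_high: float = 0.65) -> str:
    """Shape class of an LTT curve.

    Ages and counts are normalised to [0, 1] with time increasing toward the
    present, and the curve is compared against the diagonal (constant
    transposition rate).  ``L`` when the sup-norm deviation stays below
    ``delta_l`` (default: the 5% Kolmogorov-Smirnov critical value
    1.358/sqrt(n), so the call adapts to the number of events); otherwise the
    early-half event fraction decides: below ``f_low`` the median is shifted
    recent (``E``), above ``f_high`` it is shifted ancient (``C``), and a
    centred median with a significant deviation is the inflected ``S``.
    """
    n = ltt.total_events
    if n < 10:
        return "undetermined"
    oldest = float(ltt.event_ages[0])
    if oldest <= 0:
        return "undetermined"
    t = 1.0 - ltt.event_ages / oldest          # ascending in [0, 1]
    t = np.sort(t)
    if delta_l is None:
        delta_l = 1.358 / math.sqrt(n)
    i = np.arange(1, n + 1)
    ks = float(np.max(np.maximum(i / n - t, t - (i - 1) / n)))
    if ks < delta_l:
        return "L"
    f_half = float(np.mean(t <= 0.5))
    if f_half < f_low:
        return "E"
    if f_half > f_high:
        return "C"
    return "S"


def analyze_lineage(copies: list[SequenceRecord], recent_epsilon: float = 0.005,
                    max_copies: int = 500, rng_seed: int = 7
                    ) -> tuple[CopyTree, LTTCurve, DynamicsSummary]:
    """Tree, LTT curve and summary for one lineage's copies."""
    tree = build_copy_tree(copies, max_copies=max_copies, rng_seed=rng_seed)
    ltt = ltt_curve(tree)
    return tree, ltt, summarize(ltt, recent_epsilon)


def plot_ltt(ltt: LTTCurve, path, title: str = "") -> None:
    """LTT plot (cumulative events vs age, present at the right), with the
    constant-rate diagonal and the median event marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ages = ltt.event_ages
    ax.step(-ages, ltt.cumulative, where="post", color="k")
    oldest = ages[0]
    ax.plot([-oldest, 0], [0, ltt.total_events], "r--", lw=1,
            label="constant rate")
    s = summarize(ltt)
    ax.axvline(-s.median_event_age, color="r", ls=":", lw=1)
    ax.set_xlabel("age (divergence units, present at 0)")
    ax.set_ylabel("cumulative transposition events")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
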