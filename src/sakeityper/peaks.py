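"""Strain-level presence/absence analysis of binned peaks.

Replicate spectra of one strain are aggregated to a single boolean row
(a peak is "present" for a strain when it was detected — pre-fill — in at
least half of the strain's spectra, inclusive).  Per-peak association between
two classes uses a two-sided Fisher exact test on the 2x2 presence-by-class
table; prevalences are reported as percentages rounded half-up to one
decimal, matching how partial-prevalence markers are conventionally quoted
(e.g. "96 of 106 strains, 90.6%").
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact

from .preprocess import FeatureMatrix


@dataclass
class PresenceMatrix:
    """Strains x peak-bin boolean table with per-strain class labels."""

    presence: pd.DataFrame  # index strain_id, columns bin m/z, dtype bool
    class_labels: pd.Series  # index strain_id

    def __post_init__(self) -> None:
        self.class_labels = self.class_labels.reindex(self.presence.index)
        if self.class_labels.isna().any():
            missing = list(self.class_labels.index[self.class_labels.isna()])
            raise ValueError(f"strains without class label: {missing}")

    @property
    def bin_mz(self) -> np.ndarray:
        return np.asarray(self.presence.columns, dtype=float)

    def strains_of(self, cls: str) -> pd.DataFrame:
        idx = self.class_labels.index[self.class_labels == cls]
        if idx.empty:
            raise ValueError(f"no strains with class {cls!r}")
        return self.presence.loc[idx]

    def to_tsv(self, path: str | Path, config_hash: str | None = None) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if config_hash:
                fh.write(f"# config_hash={config_hash}\n")
            out = self.presence.astype(int).copy()
            out.columns = [f"{c:.1f}" for c in self.bin_mz]
            out.insert(0, "class_label", self.class_labels)
            out.index.name = "strain_id"
            out.to_csv(fh, sep="\t")


@dataclass(frozen=True)
class PeakAssociation:
    """Association of one peak bin with a two-class contrast.

    ``counts`` is the 2x2 table ``[[present_a, present_b], [absent_a,
    absent_b]]``; prevalences are percentages per class.
    """

    bin_mz: float
    counts: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    prevalence_per_class: dict[str, float]
    classes: tuple[str, str]

    def __post_init__(self) -> None:
        (pa, pb), (aa, ab) = self.counts
        if min(pa, pb, aa, ab) < 0:
            raise ValueError("counts must be non-negative")


def strain_presence(
    features: FeatureMatrix,
    manifest: pd.DataFrame,
    rule: float = 0.5,
) -> PresenceMatrix:
    """Aggregate spectrum-level detections to a strain-level presence matrix.

    A peak is present for a strain iff it was detected in at least ``rule``
    (default one half, inclusive) of that strain's spectra.
    """
    if not 0 < rule <= 1:
        raise ValueError("rule must lie in (0, 1]")
    required = {"spectrum_id", "strain_id", "class_label"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    manifest = manifest.set_index("spectrum_id")
    missing = [i for i in manifest.index if i not in features.detected.index]
    if missing:
        raise ValueError(
            f"{len(missing)} manifest spectra missing from the feature matrix, "
            f"e.g. {missing[:3]}"
        )
    det = features.detected.loc[manifest.index]
    frac = det.groupby(manifest["strain_id"], sort=True).mean()
    presence = frac >= rule
    labels = (
        manifest.groupby("strain_id", sort=True)["class_label"].agg(lambda x: x.iloc[0])
    )
    return PresenceMatrix(presence=presence, class_labels=labels)


def prevalence(present_count: int, n_strains: int) -> float:
    """Percentage of strains carrying a peak, rounded half-up to one decimal."""
    if n_strains <= 0:
        raise ValueError("n_strains must be positive")
    if not 0 <= present_count <= n_strains:
        raise ValueError("present_count must lie in [0, n_strains]")
    pct = Decimal(100 * present_count) / Decimal(n_strains)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def associate_peak(
    presence: PresenceMatrix,
    bin_mz: float,
    class_a: str,
    class_b: str,
    test: str = "fisher",
) -> PeakAssociation:
    """Two-class association of one peak bin (two-sided Fisher exact by default).

    ``test="chi2"`` switches to the chi-square test with continuity
    correction, a cheaper large-cohort alternative.
    """
    col = _find_bin(presence, bin_mz)
    a = presence.strains_of(class_a)[col]
    b = presence.strains_of(class_b)[col]
    table = np.array(
        [
            [int(a.sum()), int(b.sum())],
            [int((~a).sum()), int((~b).sum())],
        ]
    )
    if test == "fisher":
        p = float(fisher_exact(table, alternative="two-sided").pvalue)
    elif test == "chi2":
        p = float(chi2_contingency(table, correction=True).pvalue)
    else:
        raise ValueError(f"unknown association test {test!r}")
    return PeakAssociation(
        bin_mz=float(col),
        counts=((int(table[0, 0]), int(table[0, 1])), (int(table[1, 0]), int(table[1, 1]))),
        p_value=p,
        prevalence_per_class={
            class_a: prevalence(int(table[0, 0]), len(a)),
            class_b: prevalence(int(table[0, 1]), len(b)),
        },
        classes=(class_a, class_b),
    )


def _find_bin(presence: PresenceMatrix, bin_mz: float) -> float:
    cols = presence.bin_mz
    i = int(np.argmin(np.abs(cols - bin_mz)))
    if abs(cols[i] - bin_mz) > 0.01 * bin_mz:
        raise KeyError(f"no peak bin near {bin_mz} Da (closest: {cols[i]:.1f})")
    return float(presence.presence.columns[i])


def discriminative_peaks(
    presence: PresenceMatrix,
    class_a: str,
    class_b: str,
    alpha: float = 0.01,
    k: int = 10,
    test: str = "fisher",
    bh_correction: bool = False,
) -> list[PeakAssociation]:
    """Rank peak bins by association p-value between two classes.

    Returns the peaks with p < ``alpha`` (on Benjamini-Hochberg-adjusted
    p-values when ``bh_correction``), sorted by ascending p (ties broken by
    ascending m/z), truncated to the top ``k``.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    assocs = [
        associate_peak(presence, mz, class_a, class_b, test=test)
        for mz in presence.bin_mz
    ]
    if bh_correction:
        from scipy.stats import false_discovery_control

        adjusted = false_discovery_control([a.p_value for a in assocs], method="bh")
        assocs = [
            PeakAssociation(a.bin_mz, a.counts, float(q), a.prevalence_per_class, a.classes)
            for a, q in zip(assocs, adjusted)
        ]
    # alpha = 1 means "no filter": include peaks with p exactly 1.0
    selected = [a for a in assocs if a.p_value < alpha or alpha >= 1.0]
    selected.sort(key=lambda a: (a.p_value, a.bin_mz))
    return selected[:k]


def associations_table(assocs: Sequence[PeakAssociation]) -> pd.DataFrame:
    """Flatten associations into a tidy DataFrame (one row per peak bin)."""
    rows = []
    for a in assocs:
        ca, cb = a.classes
        rows.append(
            {
                "bin_mz": round(a.bin_mz, 1),
                f"present_{ca}": a.counts[0][0],
                f"present_{cb}": a.counts[0][1],
                f"absent_{ca}": a.counts[1][0],
                f"absent_{cb}": a.counts[1][1],
                f"prevalence_{ca}_pct": a.prevalence_per_class[ca],
                f"prevalence_{cb}_pct": a.prevalence_per_class[cb],
                "p_value": a.p_value,
            }
        )
    return pd.DataFrame(rows)


def pseudo_gel(
    presence: PresenceMatrix,
    path: str | Path,
    classes: Sequence[str] | None = None,
) -> None:
    """Write a pseudo-gel raster (strains x m/z presence) as a PNG image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if classes is not None:
        keep = presence.class_labels.isin(list(classes))
        mat = presence.presence.loc[keep.index[keep]]
        labels = presence.class_labels.loc[keep.index[keep]]
    else:
        mat, labels = presence.presence, presence.class_labels
    order = labels.sort_values(kind="stable").index
    fig, ax = plt.subplots(figsize=(10, 6))
    ax.imshow(
        mat.loc[order].to_numpy(), aspect="auto", cmap="Greys", interpolation="nearest"
    )
    ax.set_xlabel("peak bin (m/z)")
    ax.set_ylabel("strain")
    ticks = np.linspace(0, mat.shape[1] - 1, min(12, mat.shape[1])).astype(int)
    ax.set_xticks(ticks)
    ax.set_xticklabels([f"{presence.bin_mz[t]:.0f}" for t in ticks], rotation=90)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
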