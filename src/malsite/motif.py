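"""Positional residue-frequency summaries and two-sample enrichment.

Malonylated and non-malonylated peptide sets can look indistinguishable in a
plain sequence logo yet differ sharply position by position.  This module
computes per-position residue frequencies and, between two window sets, a
per-(position, residue) two-sample test on the 0/1 occurrence indicators —
the same comparison popularized by the Two Sample Logo tool.  Welch's
unequal-variance t-test is used (the indicator variances of the two sets
generally differ); pairs with p below ``alpha`` (default 0.05) are reported
as enriched in whichever set has the higher frequency.

The dummy residue X is treated as a 21st residue: terminal-padding signal is
real and visible in datasets with short proteins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .windows import ALPHABET, PeptideWindow, WindowConfig


def position_labels(length: int, xi: int | None = None) -> list[int]:
    """Window position labels -xi..0..+eta for a window of given length."""
    if xi is None:
        xi = WindowConfig().xi if length == WindowConfig().length else length // 2
    return list(range(-xi, length - xi))


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """21 x L residue-frequency matrix with position-labeled columns."""

    frame: pd.DataFrame  # rows: 21 residues; columns: position labels
    n: int


def frequency_matrix(
    windows: Sequence[PeptideWindow], config: WindowConfig = WindowConfig()
) -> PositionFrequencyMatrix:
    """Empirical residue frequency per window position; columns sum to 1."""
    if not windows:
        raise ValueError("frequency matrix requires at least one window")
    lengths = {len(w) for w in windows}
    if len(lengths) > 1:
        raise ValueError(f"mixed window lengths: {sorted(lengths)}")
    L = lengths.pop()
    counts = np.zeros((len(ALPHABET), L))
    index = {aa: i for i, aa in enumerate(ALPHABET)}
    for w in windows:
        for j, ch in enumerate(w.residues):
            counts[index[ch], j] += 1
    freq = counts / len(windows)
    cols = position_labels(L, config.xi if L == config.length else None)
    frame = pd.DataFrame(freq, index=list(ALPHABET), columns=cols)
    return PositionFrequencyMatrix(frame=frame, n=len(windows))


@dataclass(frozen=True)
class EnrichmentResult:
    """One significant (position, residue) difference between two sets."""

    position: int
    residue: str
    direction: str  # "enriched" (in first set) or "depleted"
    statistic: float
    pvalue: float
    freq_positive: float
    freq_negative: float


def two_sample_enrichment(
    positives: Sequence[PeptideWindow],
    negatives: Sequence[PeptideWindow],
    alpha: float = 0.05,
    config: WindowConfig = WindowConfig(),
    correction: str | None = None,
) -> list[EnrichmentResult]:
    """Per-(position, residue) Welch t-test on occurrence indicators.

    Reports pairs with p < alpha, signed by the frequency difference:
    ``enriched`` means over-represented in ``positives``.  ``correction``
    may be ``"bonferroni"`` (no correction by default, matching the
    convention of the web tool this mirrors).  When both sets are constant
    at a position/residue: an identical constant is skipped, while a
    differing constant (0% vs 100%) is reported with p = 0.
    """
    if not positives or not negatives:
        raise ValueError("both window sets must be non-empty")
    lengths = {len(w) for w in list(positives) + list(negatives)}
    if len(lengths) > 1:
        raise ValueError(f"mixed window lengths: {sorted(lengths)}")
    L = lengths.pop()
    labels = position_labels(L, config.xi if L == config.length else None)

    tested: list[tuple[int, str, float, float, float, float]] = []
    for j, pos_label in enumerate(labels):
        for aa in ALPHABET:
            a = np.array([1.0 if w.residues[j] == aa else 0.0 for w in positives])
            b = np.array([1.0 if w.residues[j] == aa else 0.0 for w in negatives])
            fa, fb = float(a.mean()), float(b.mean())
            if a.std() == 0 and b.std() == 0:
                if fa == fb:
                    continue  # identical constants: no evidence of difference
                stat, p = float("inf") if fa > fb else float("-inf"), 0.0
            else:
                stat, p = stats.ttest_ind(a, b, equal_var=False)
                stat, p = float(stat), float(p)
            tested.append((pos_label, aa, stat, p, fa, fb))

    if correction == "bonferroni":
        m = len(tested)
        tested = [(pl, aa, s, min(p * m, 1.0), fa, fb) for pl, aa, s, p, fa, fb in tested]
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")

    results = [
        EnrichmentResult(
            position=pl,
            residue=aa,
            direction="enriched" if fa > fb else "depleted",
            statistic=s,
            pvalue=p,
            freq_positive=fa,
            freq_negative=fb,
        )
        for pl, aa, s, p, fa, fb in tested
        if p < alpha and fa != fb
    ]
    results.sort(key=lambda r: (r.pvalue, r.position, r.residue))
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "position": r.position,
                "residue": r.residue,
                "direction": r.direction,
                "statistic": round(r.statistic, 6) if np.isfinite(r.statistic) else r.statistic,
                "pvalue": r.pvalue,
                "freq_positive": round(r.freq_positive, 6),
                "freq_negative": round(r.freq_negative, 6),
            }
            for r in results
        ],
        columns=[
            "position", "residue", "direction", "statistic",
            "pvalue", "freq_positive", "freq_negative",
        ],
    )


def logo_plot(pfm: PositionFrequencyMatrix, path: str, title: str = "") -> None:
    """Optional stacked-bar frequency plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = pfm.frame
    fig, ax = plt.subplots(figsize=(10, 4))
    bottom = np.zeros(frame.shape[1])
    for aa in frame.index:
        vals = frame.loc[aa].to_numpy()
        ax.bar([str(c) for c in frame.columns], vals, bottom=bottom, label=aa)
        bottom += vals
    ax.set_xlabel("window position")
    ax.set_ylabel("residue frequency")
    if title:
        ax.set_title(title)
    ax.legend(ncol=7, fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
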