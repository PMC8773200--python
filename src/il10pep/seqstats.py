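"""Class-comparison sequence statistics.

Two analyses compare IL-10-inducing (label 1) and non-inducing (label 0)
peptides:

* :func:`composition_comparison` — the mean per-peptide amino-acid
  composition of each class, their difference, and a Welch two-sample
  t-test per residue (the average-composition bar-plot statistic).
* :func:`position_enrichment` — two-sample-logo position statistics over a
  16-position window: positions 1-8 are the N-terminal window (first
  residues), positions 9-16 the C-terminal window (last residues, aligned
  to the peptide end). Per position x residue, occurrence indicators are
  compared between classes with a Welch t-test; cells with p below alpha
  form the enriched/depleted sets.

Variable lengths: each peptide contributes its first ``min(8, N)`` residues
to the N-window and its last ``min(8, N)`` residues to the C-window, so
peptides shorter than 16 contribute some residues to both windows
(dropping them would bias the composition). The windows never read outside
a peptide. No multiple-testing correction is applied by default (matching
the raw p < 0.05 logo-scaling convention); a Bonferroni option exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .descriptors import aac
from .errors import ValidationError
from .io import ALPHABET, LabeledDataset

__all__ = ["CompositionComparison", "PositionEnrichment",
           "composition_comparison", "position_enrichment",
           "plot_enrichment"]

WINDOW = 8  # residues per terminal window


@dataclass
class CompositionComparison:
    """Per-residue class composition means, difference and p-values."""

    table: pd.DataFrame  # index residue; mean_pos, mean_neg, difference, p_value

    def significant(self, alpha: float = 0.05) -> list[str]:
        return list(self.table.index[self.table["p_value"] < alpha])


@dataclass
class PositionEnrichment:
    """Two-sample-logo statistics per (window position, residue)."""

    table: pd.DataFrame  # position, window, residue, freq_pos, freq_neg,
    #                      direction, p_value, significant
    alpha: float

    def significant_cells(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def _welch_binary(a: np.ndarray, b: np.ndarray) -> float:
    """Welch t-test p-value robust to zero-variance degeneracy.

    If both samples are constant the test statistic is undefined: return
    1.0 when the (degenerate) means agree, 0.0 when they differ —
    complete separation is reported as p below any floor.
    """
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    p = stats.ttest_ind(a, b, equal_var=False).pvalue
    return float(p) if np.isfinite(p) else 1.0


def _split_classes(dataset: LabeledDataset
                   ) -> tuple[LabeledDataset, LabeledDataset]:
    y = dataset.labels
    if y.sum() == 0 or y.sum() == y.size:
        raise ValidationError(
            "class comparison needs both classes present"
        )
    return (dataset.subset(np.flatnonzero(y == 1)),
            dataset.subset(np.flatnonzero(y == 0)))


def composition_comparison(dataset: LabeledDataset) -> CompositionComparison:
    """Mean per-peptide composition of each class plus Welch t-tests.

    Class means are averages of per-peptide composition vectors, so each
    class mean sums to 1.
    """
    pos, neg = _split_classes(dataset)
    comp_pos = np.stack([aac(s) for s in pos.sequences])
    comp_neg = np.stack([aac(s) for s in neg.sequences])
    pvals = [_welch_binary(comp_pos[:, i], comp_neg[:, i]) for i in range(20)]
    table = pd.DataFrame({
        "mean_pos": comp_pos.mean(axis=0),
        "mean_neg": comp_neg.mean(axis=0),
        "p_value": pvals,
    }, index=pd.Index(list(ALPHABET), name="residue"))
    table["difference"] = table["mean_pos"] - table["mean_neg"]
    return CompositionComparison(table[["mean_pos", "mean_neg",
                                        "difference", "p_value"]])


def _window_indicators(sequences: list[str]) -> dict[int, np.ndarray]:
    """Per window position (1..16): (n_covering, 20) occurrence indicators.

    Positions 1..8 index from the N-terminus, 9..16 are the last eight
    residues aligned to the C-terminus (position 16 = final residue).
    """
    out: dict[int, list[np.ndarray]] = {p: [] for p in range(1, 2 * WINDOW + 1)}
    for seq in sequences:
        n = len(seq)
        m = min(WINDOW, n)
        for j in range(m):  # N-window
            row = np.zeros(20)
            row[ALPHABET.index(seq[j])] = 1.0
            out[j + 1].append(row)
        for j in range(m):  # C-window, aligned to the end
            row = np.zeros(20)
            row[ALPHABET.index(seq[n - m + j])] = 1.0
            out[2 * WINDOW - m + j + 1].append(row)
    return {p: np.stack(rows) if rows else np.zeros((0, 20))
            for p, rows in out.items()}


def position_enrichment(dataset: LabeledDataset, alpha: float = 0.05,
                        bonferroni: bool = False) -> PositionEnrichment:
    """Two-sample-logo statistics over the 16-position terminal window."""
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    pos, neg = _split_classes(dataset)
    for name, part in (("positive", pos), ("negative", neg)):
        if max(len(p) for p in part.peptides) < WINDOW:
            raise ValidationError(
                f"{name} class has no peptide of length >= {WINDOW}"
            )
    ind_pos = _window_indicators(pos.sequences)
    ind_neg = _window_indicators(neg.sequences)
    n_cells = 2 * WINDOW * 20
    rows = []
    for p in range(1, 2 * WINDOW + 1):
        a, b = ind_pos[p], ind_neg[p]
        freq_a = a.mean(axis=0) if a.size else np.zeros(20)
        freq_b = b.mean(axis=0) if b.size else np.zeros(20)
        for r, residue in enumerate(ALPHABET):
            pval = _welch_binary(a[:, r], b[:, r]) if a.size and b.size else 1.0
            if bonferroni:
                pval = min(1.0, pval * n_cells)
            diff = freq_a[r] - freq_b[r]
            rows.append({
                "position": p,
                "window": "N" if p <= WINDOW else "C",
                "residue": residue,
                "freq_pos": freq_a[r],
                "freq_neg": freq_b[r],
                "direction": int(np.sign(diff)),
                "p_value": pval,
                "significant": bool(pval < alpha and diff != 0),
            })
    return PositionEnrichment(pd.DataFrame(rows), alpha)


def plot_enrichment(enrichment: PositionEnrichment, ax=None):
    """Diverging per-position bar panel of significant residue enrichments.

    Enriched residues (positive class) stack upward, depleted downward;
    bar heights are the class frequency differences.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    sig = enrichment.significant_cells()
    for p in range(1, 2 * WINDOW + 1):
        up = down = 0.0
        cells = sig[sig["position"] == p]
        for _, row in cells.sort_values("residue").iterrows():
            diff = row["freq_pos"] - row["freq_neg"]
            base = up if diff > 0 else down
            ax.bar(p, abs(diff), bottom=base if diff > 0 else base - abs(diff),
                   color="tab:red" if diff > 0 else "tab:blue", width=0.8)
            ax.text(p, base + diff / 2, row["residue"], ha="center",
                    va="center", fontsize=7)
            if diff > 0:
                up += diff
            else:
                down -= abs(diff)
    ax.axhline(0.0, color="black", lw=0.8)
    ax.axvline(WINDOW + 0.5, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("window position (1-8 N-terminal, 9-16 C-terminal)")
    ax.set_ylabel("frequency difference (pos - neg)")
    ax.set_title(f"Residue enrichment, p < {enrichment.alpha}")
    return ax
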