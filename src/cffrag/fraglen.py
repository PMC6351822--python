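"""Fragment-length distributions.

Plasma cfDNA is dominated by chromatosome-protected fragments, so the length
histogram of a healthy library shows a strong 166–175 bp modal mass. Group
histograms are count-sums over the member libraries (replicates pooled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SampleLibrary

__all__ = ["LengthHistogram", "length_histogram", "modal_length", "merge_histograms"]


@dataclass
class LengthHistogram:
    """Integer-length fragment counts."""

    counts: pd.Series  # index: length (bp), values: counts

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        freq = self.counts / self.total if self.total else self.counts * 0.0
        return pd.DataFrame(
            {"length": self.counts.index, "count": self.counts.values, "frequency": freq.values}
        )


def length_histogram(lib: SampleLibrary) -> LengthHistogram:
    """Tally of end - start over all fragments."""
    if lib.library_size == 0:
        raise ValueError("cannot histogram an empty library")
    lengths = lib.ends() - lib.starts()
    values, counts = np.unique(lengths, return_counts=True)
    return LengthHistogram(pd.Series(counts, index=values).sort_index())


def merge_histograms(histograms: list[LengthHistogram]) -> LengthHistogram:
    """Group-level histogram: count-sum over member libraries."""
    if not histograms:
        raise ValueError("need at least one histogram")
    total = histograms[0].counts.copy()
    for h in histograms[1:]:
        total = total.add(h.counts, fill_value=0)
    return LengthHistogram(total.astype(int).sort_index())


def modal_length(hist: LengthHistogram) -> int:
    """Smallest fragment length achieving the maximum count."""
    if hist.total == 0:
        raise ValueError("empty histogram has no mode")
    counts = hist.counts
    return int(counts.index[np.argmax(counts.values)])  # index sorted: first max = smallest
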