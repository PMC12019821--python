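"""Retrospective assignment of imaging readouts to (cardiac bin, respiratory state).

Every imaging readout is binned independently of its position in the spiral
interleave: the cardiac bin is the 50 ms window elapsed since the preceding
trigger, the respiratory state the amplitude quartile of the self-gated
respiratory signal at the readout time.  Readouts before the first or after
the last trigger, and readouts falling beyond the nominal number of cardiac
bins (long beats), are discarded rather than folded into the last bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .selfgating import TriggerList

logger = logging.getLogger(__name__)

__all__ = ["BinAssignment", "n_cardiac_bins", "assign_bins", "occupancy_report"]

DEFAULT_BIN_WIDTH_MS = 50.0


@dataclass
class BinAssignment:
    """Per-imaging-readout (cardiac bin, respiratory state) labels."""

    cardiac_bin: np.ndarray  # (n,) int, -1 where discarded
    resp_state: np.ndarray  # (n,) int
    discard_mask: np.ndarray  # (n,) bool
    n_cardiac_bins: int
    n_resp_states: int
    bin_width: float  # ms

    @property
    def n_readouts(self) -> int:
        return self.cardiac_bin.size

    @property
    def n_assigned(self) -> int:
        return int((~self.discard_mask).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "readout": np.arange(self.n_readouts),
                "cardiac_bin": self.cardiac_bin,
                "resp_state": self.resp_state,
                "discarded": self.discard_mask,
            }
        )


def n_cardiac_bins(median_rr: float, bin_width: float = DEFAULT_BIN_WIDTH_MS) -> int:
    """Number of cardiac phases: floor(median RR / bin width)."""
    if median_rr < bin_width:
        raise ValueError(f"median RR {median_rr} ms shorter than bin width {bin_width} ms")
    return int(np.floor(median_rr / bin_width))


def assign_bins(
    readout_timestamps: np.ndarray,
    triggers: TriggerList,
    resp_states: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH_MS,
    n_bins: int | None = None,
) -> BinAssignment:
    """Per-readout cardiac/respiratory binning.

    For a readout at time ``t`` with preceding trigger ``T`` the cardiac bin
    is ``floor((t - T) / bin_width)``.  ``n_bins`` defaults to
    ``floor(median RR / bin_width)``.
    """
    t = np.asarray(readout_timestamps, dtype=float)
    trig = np.asarray(triggers.times, dtype=float)
    if trig.size == 0:
        raise ValueError("empty trigger list")
    resp_states = np.asarray(resp_states)
    if resp_states.shape != t.shape:
        raise ValueError("resp_states must be defined for every readout")
    if n_bins is None:
        n_bins = n_cardiac_bins(triggers.median_rr_ms(), bin_width)

    idx = np.searchsorted(trig, t, side="right") - 1
    before_first = idx < 0
    after_last = t >= trig[-1] if trig.size > 1 else np.ones_like(t, bool)
    safe_idx = np.clip(idx, 0, trig.size - 1)
    elapsed_ms = (t - trig[safe_idx]) * 1000.0
    cbin = np.floor(elapsed_ms / bin_width).astype(np.int64)
    long_beat = cbin >= n_bins
    discard = before_first | after_last | long_beat
    cbin[discard] = -1

    return BinAssignment(
        cardiac_bin=cbin,
        resp_state=resp_states.astype(np.int64),
        discard_mask=discard,
        n_cardiac_bins=int(n_bins),
        n_resp_states=int(resp_states.max()) + 1,
        bin_width=float(bin_width),
    )


def occupancy_report(assignment: BinAssignment) -> dict:
    """Per-bin readout counts plus the discard fraction."""
    counts = np.zeros((assignment.n_cardiac_bins, assignment.n_resp_states), dtype=np.int64)
    keep = ~assignment.discard_mask
    np.add.at(counts, (assignment.cardiac_bin[keep], assignment.resp_state[keep]), 1)
    discard_fraction = float(assignment.discard_mask.mean()) if assignment.n_readouts else 0.0
    report = {
        "counts": counts,
        "discard_fraction": discard_fraction,
        "n_total": assignment.n_readouts,
        "n_assigned": int(keep.sum()),
        "min_bin_count": int(counts.min()) if counts.size else 0,
    }
    logger.info(
        "bin occupancy: %d/%d readouts assigned (%.1f%% discarded), min bin count %d",
        report["n_assigned"], report["n_total"], 100 * discard_fraction, report["min_bin_count"],
    )
    return report
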