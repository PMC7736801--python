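"""Two-channel classification of droplets into empty / dCTP / 5mdCTP.

The modified-base detection chemistry uses two detection oligo sets sharing
a capture site: channel 1 fluoresces whenever a cytosine (methylated or not)
is captured, while channel 2 relies on a modification-sensitive restriction
step that 5-methylcytosine blocks, so it fluoresces for unmethylated dCTP
only.  Per-channel occupancy calls therefore separate three populations:

========  ========  =========
channel1  channel2  label
========  ========  =========
  -         -       empty
  +         +       dCTP
  +         -       5mdCTP
  -         +       inconsistent (flagged, never merged)
========  ========  =========

The (-, +) combination has no chemical interpretation; its rate estimates
the modification-call error of the assay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .mixture import MixtureFit, call_occupancy
from .simulate import DropletRecord

__all__ = ["MethylCall", "classify_two_channel", "label_fractions"]

_TRUTH_TABLE = {
    (False, False): "empty",
    (True, True): "dCTP",
    (True, False): "5mdCTP",
    (False, True): "inconsistent",
}


@dataclass(frozen=True)
class MethylCall:
    index: int
    label: str
    ch1_posterior: float
    ch2_posterior: float


def classify_two_channel(
    records: Sequence[DropletRecord],
    fits: Mapping[str, MixtureFit],
) -> list[MethylCall]:
    """Classify two-channel droplets by per-channel occupancy thresholding.

    Classification is deliberately per-channel (each channel's own mixture
    fit and posterior), not a joint 2-D clustering: the two channels report
    independent chemical events.
    """
    missing = {"ch1", "ch2"} - set(fits)
    if missing:
        raise ValueError(f"missing mixture fit for channel(s) {sorted(missing)}")
    for rec in records:
        if "ch1" not in rec.intensity or "ch2" not in rec.intensity:
            raise ValueError(f"droplet {rec.index} lacks a methylation channel")
    calls = call_occupancy(records, {"ch1": fits["ch1"], "ch2": fits["ch2"]})
    return [
        MethylCall(
            index=c.index,
            label=_TRUTH_TABLE[(c.occupied["ch1"], c.occupied["ch2"])],
            ch1_posterior=c.posterior["ch1"],
            ch2_posterior=c.posterior["ch2"],
        )
        for c in calls
    ]


def label_fractions(calls: Sequence[MethylCall]) -> dict[str, float]:
    """Population fractions per label (including 'inconsistent')."""
    if not calls:
        raise ValueError("no calls given")
    n = len(calls)
    return {
        lab: sum(c.label == lab for c in calls) / n
        for lab in ("empty", "dCTP", "5mdCTP", "inconsistent")
    }
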