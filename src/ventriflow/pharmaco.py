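"""Drug-response quantification for paired pre/post recordings.

The chronotropic/inotropic response of a ventricle is expressed per metric
as the ratio of the post-incubation value to its own pre-drug control and as
the equivalent percent change, 100·(ratio − 1). Pairing each ventricle with
its own baseline mirrors the control-then-treatment measurement protocol;
no cross-ventricle pooling happens here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import UndefinedBaselineError
from .flowmetrics import RecordingMetrics

__all__ = ["DrugResponse", "percent_change", "RESPONSE_METRICS"]

#: RecordingMetrics fields a drug response is computed over.
RESPONSE_METRICS = (
    "frequency",
    "mean_stroke_volume",
    "theoretical_cardiac_output",
    "max_volume_flow",
)


@dataclass(frozen=True)
class DrugResponse:
    """Post/pre ratios and percent changes per pump-function metric.

    Invariant: ``percent[m] == 100 * (ratio[m] - 1)`` for every metric, with
    increases positive and decreases negative.
    """

    ratio: dict[str, float] = field(default_factory=dict)
    percent: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"ratio": dict(self.ratio), "percent": dict(self.percent)}


def percent_change(pre: RecordingMetrics, post: RecordingMetrics) -> DrugResponse:
    """Normalized drug response of one ventricle.

    Raises
    ------
    UndefinedBaselineError
        If any pre-drug metric is zero or negative, naming the metric.
    """
    ratio: dict[str, float] = {}
    percent: dict[str, float] = {}
    for name in RESPONSE_METRICS:
        pre_val = getattr(pre, name)
        post_val = getattr(post, name)
        if pre_val <= 0:
            raise UndefinedBaselineError(
                f"pre-drug {name} is {pre_val}; ratio to it is undefined"
            )
        r = post_val / pre_val
        ratio[name] = r
        percent[name] = 100.0 * (r - 1.0)
    return DrugResponse(ratio=ratio, percent=percent)
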