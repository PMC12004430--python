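"""Canonical units and the single conversion constant.

The pipeline works in seconds, µL/min for instantaneous flow and nL for
per-beat volumes. Integrating a flow q [µL/min] over time t [s] yields
µL·s/min; one µL·s/min equals 1000/60 nL. This factor is applied in exactly
one place (`NL_PER_UL_MIN_S`) so the unit chain is auditable.
"""

#: nL of volume per (µL/min × s) of integrated flow.
NL_PER_UL_MIN_S: float = 1000.0 / 60.0

#: Canonical unit labels.
TIME_UNIT = "s"
FLOW_UNIT = "uL/min"
VOLUME_UNIT = "nL"
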