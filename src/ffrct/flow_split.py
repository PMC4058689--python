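"""Baseline flow distribution from the generalized Murray law.

In a healthy (stenosis-free) tree, outlet flow is assumed to scale with a
power k of the outlet diameter: Q_i proportional to d_i^k. The classical
Murray law has k = 3; the generalized coronary value k = 7/3 is the
default here.
"""

from __future__ import annotations

from dataclasses import dataclass

from .geometry import CoronaryTree


class FlowSplitError(ValueError):
    pass


@dataclass(frozen=True)
class FlowSplit:
    """Dimensionless outlet flow fractions; they sum to 1."""

    fractions: dict  # outlet id -> fraction
    exponent: float

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-12:
            raise FlowSplitError(f"fractions sum to {total}, not 1")
        if any(f <= 0 for f in self.fractions.values()):
            raise FlowSplitError("every fraction must be positive")


def murray_split(outlet_diameters: dict, exponent: float = 7.0 / 3.0) -> FlowSplit:
    """fraction_i = d_i^k / sum_j d_j^k over the given outlet diameters (mm)."""
    if exponent <= 0:
        raise FlowSplitError(f"Murray exponent must be positive, got {exponent}")
    if not outlet_diameters:
        raise FlowSplitError("no outlets given")
    for oid, d in outlet_diameters.items():
        if d <= 0:
            raise FlowSplitError(f"outlet {oid!r} has nonpositive diameter {d}")
    powers = {oid: float(d) ** exponent for oid, d in outlet_diameters.items()}
    total = sum(powers.values())
    fractions = {oid: p / total for oid, p in powers.items()}
    # renormalize the largest fraction to absorb float round-off
    top = max(fractions, key=fractions.get)
    fractions[top] += 1.0 - sum(fractions.values())
    return FlowSplit(fractions=fractions, exponent=exponent)


def outlet_diameters(tree: CoronaryTree) -> dict:
    """Terminal (distal-end) diameter of every outlet segment, mm."""
    return {oid: float(tree.segment(oid).samples_d[-1]) for oid in tree.outlets}


def tree_murray_split(tree: CoronaryTree, exponent: float = 7.0 / 3.0) -> FlowSplit:
    return murray_split(outlet_diameters(tree), exponent)


def assign_baseline_flows(tree: CoronaryTree, split: FlowSplit,
                          total_inflow_ml_min: float) -> dict:
    """Distribute a total inflow (mL/min) over the tree outlets."""
    if set(split.fractions) != set(tree.outlets):
        raise FlowSplitError(
            f"split outlets {sorted(split.fractions)} do not match "
            f"tree outlets {sorted(tree.outlets)}")
    return {oid: frac * total_inflow_ml_min for oid, frac in split.fractions.items()}
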