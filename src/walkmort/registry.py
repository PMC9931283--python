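"""Registry of the 76 per-epoch time-domain sensor features.

The feature set splits into two halves of 38: the statistics computed by the
UK Biobank accelerometer software on the raw 100 Hz stream
(``biobank_time_domain``), and a further 38 derived statistics (per-axis
variants plus RMS / TAC / MCR / MMCR, ``derived``).  Feature names follow the
axis-prefix convention used in the study tables (``ENMOtrunc``, ``xSd``,
``yMMCR``, ...).  All downstream tables and vectors are ordered by this
registry.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class FeatureSpec:
    """A single named feature with its provenance group and axis tag."""

    name: str
    group: str  # {"biobank_time_domain", "derived"}
    axis: str  # {"magnitude", "x", "y", "z", "cross-axis", "orientation"}


_AXES = ("x", "y", "z")


def _build_registry() -> tuple[FeatureSpec, ...]:
    specs: list[FeatureSpec] = []

    def a(name: str, axis: str) -> None:
        specs.append(FeatureSpec(name, "biobank_time_domain", axis))

    def b(name: str, axis: str) -> None:
        specs.append(FeatureSpec(name, "derived", axis))

    # --- Biobank time-domain half (38) ---
    a("ENMOtrunc", "magnitude")
    a("Mean", "magnitude")
    for ax in _AXES:
        a(f"{ax}Mean", ax)
    a("Sd", "magnitude")
    for ax in _AXES:
        a(f"{ax}Sd", ax)
    a("MAD", "magnitude")
    a("MPD", "magnitude")
    a("kurt", "magnitude")
    a("skew", "magnitude")
    for name in ("Min", "Max", "25thp", "Median", "75thp", "autocorr", "coefvariation"):
        a(name, "magnitude")
    for ax in _AXES:
        a(f"{ax}Range", ax)
    for pair in ("xy", "xz", "yz"):
        a(f"Cov{pair}", "cross-axis")
    for pair in ("xy", "xz", "yz"):
        a(f"corr{pair}", "cross-axis")
    for angle in ("pitch", "roll", "yaw"):
        a(f"{angle}g", "orientation")
    for angle in ("pitch", "roll", "yaw"):
        a(f"sd{angle}", "orientation")
    for angle in ("pitch", "roll", "yaw"):
        a(f"avg{angle}", "orientation")

    # --- Derived half (38) ---
    b("ENMOabs", "magnitude")
    for name in ("Min", "Max", "25thp", "Median", "75thp", "autocorr", "coefvariation"):
        for ax in _AXES:
            b(f"{ax}{name}", ax)
    for name in ("RMS", "TAC", "MCR", "MMCR"):
        b(name, "magnitude")
        for ax in _AXES:
            b(f"{ax}{name}", ax)

    return tuple(specs)


FEATURE_REGISTRY: tuple[FeatureSpec, ...] = _build_registry()
FEATURE_NAMES: tuple[str, ...] = tuple(s.name for s in FEATURE_REGISTRY)
N_FEATURES: int = len(FEATURE_REGISTRY)


def feature_names(group: str | None = None) -> list[str]:
    """Registry-ordered feature names, optionally restricted to one group."""
    if group is None:
        return list(FEATURE_NAMES)
    valid = {"biobank_time_domain", "derived"}
    if group not in valid:
        raise ValueError(f"unknown feature group {group!r}; expected one of {sorted(valid)}")
    return [s.name for s in FEATURE_REGISTRY if s.group == group]
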