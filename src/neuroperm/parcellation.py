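"""Default 36-region functional parcellation and resting-state network presets.

The parcellation is a high-level grey-matter scheme of 36 unilateral regions
(18 per hemisphere, white matter excluded).  Three canonical mouse
resting-state networks are bundled: the default mode network (DMN), the
salience network, and an anxiety/fear network built from 20 a-priori
regions (10 per hemisphere) spanning limbic, striatal and brainstem areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field


# 18 region names; each exists in a left ("L ") and right ("R ") copy.
_BASE_REGIONS = (
    "cingulate cortex",
    "prefrontal cortex",
    "amygdala",
    "pallidum and accumbens",
    "striatum",
    "hypothalamus",
    "dorsal hippocampus",
    "ventral hippocampus",
    "periaqueductal grey",
    "brain stem",
    "colliculus",
    "sensory cortex",
    "motor cortex",
    "insular cortex",
    "auditory cortex",
    "visual cortex",
    "thalamus",
    "septum",
)


def bilateral(names: tuple[str, ...] | list[str]) -> list[str]:
    """Expand base region names to 'L name'/'R name' pairs (left first)."""
    out = [f"L {n}" for n in names]
    out += [f"R {n}" for n in names]
    return out


#: The default 36-ROI parcellation: 18 left then 18 right regions.
DEFAULT_ROI_NAMES: list[str] = bilateral(_BASE_REGIONS)


@dataclass(frozen=True)
class NetworkDefinition:
    """A named subnetwork: a set of >=2 ROI names within a parcellation."""

    name: str
    rois: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.rois) < 2:
            raise ValueError(f"network {self.name!r} needs >=2 ROIs")
        if len(set(self.rois)) != len(self.rois):
            raise ValueError(f"network {self.name!r} has duplicate ROIs")

    def validate_against(self, roi_names: list[str]) -> None:
        missing = [r for r in self.rois if r not in roi_names]
        if missing:
            raise ValueError(
                f"network {self.name!r} references unknown ROIs: {missing}"
            )

    def indices(self, roi_names: list[str]) -> list[int]:
        self.validate_against(roi_names)
        return [roi_names.index(r) for r in self.rois]


#: Default mode network: bilateral prefrontal, cingulate, dorsal hippocampus.
DMN = NetworkDefinition(
    "DMN",
    tuple(bilateral(("prefrontal cortex", "cingulate cortex", "dorsal hippocampus"))),
)

#: Salience network: bilateral cingulate, amygdala, striatum.
SALIENCE = NetworkDefinition(
    "salience",
    tuple(bilateral(("cingulate cortex", "amygdala", "striatum"))),
)

# The 10 anxiety/fear-related base regions (20 ROIs bilaterally).
_ANXIETY_BASE = (
    "cingulate cortex",
    "prefrontal cortex",
    "amygdala",
    "pallidum and accumbens",
    "striatum",
    "hypothalamus",
    "dorsal hippocampus",
    "ventral hippocampus",
    "periaqueductal grey",
    "brain stem",
)

#: Anxiety network: 20 regions (10 left + 10 right).
ANXIETY = NetworkDefinition("anxiety", tuple(bilateral(_ANXIETY_BASE)))

#: Seed list for the a-priori node-strength analysis (20 regions).
ANXIETY_SEEDS: list[str] = list(ANXIETY.rois)

#: Bundled network presets, keyed by name.
DEFAULT_NETWORKS: dict[str, NetworkDefinition] = {
    n.name: n for n in (DMN, SALIENCE, ANXIETY)
}
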