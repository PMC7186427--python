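"""Frontal-striatum-thalamus pathway definition.

The analysis operates on ten bilateral regions of interest spanning the
cortico-striato-pallido-thalamic glutamatergic loop: dorsolateral
prefrontal cortex (dLPFC, represented by the dorsolateral superior
frontal gyrus), caudate, putamen, pallidum and thalamus, each in the
left and right hemisphere.  Directed connectivity is examined over all
ordered pairs of distinct regions, i.e. R * (R - 1) = 90 connections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DEFAULT_REGIONS: tuple[str, ...] = (
    "L.dLPFC",
    "R.dLPFC",
    "L.Caudate",
    "R.Caudate",
    "L.Putamen",
    "R.Putamen",
    "L.Pallidum",
    "R.Pallidum",
    "L.Thalamus",
    "R.Thalamus",
)

#: The three effect families tested on every directed connection.
EFFECT_FAMILIES: tuple[str, ...] = ("snp1", "snp2", "interaction")


@dataclass(frozen=True)
class PathwayDefinition:
    """Ordered set of region labels defining the analysed pathway."""

    region_labels: tuple[str, ...] = DEFAULT_REGIONS

    def __post_init__(self) -> None:
        labels = tuple(self.region_labels)
        object.__setattr__(self, "region_labels", labels)
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique")
        if len(labels) < 2:
            raise ValueError("a pathway needs at least two regions")

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    def connections(self) -> list[tuple[str, str]]:
        """All ordered (source, target) pairs of distinct regions."""
        return [
            (src, tgt)
            for src in self.region_labels
            for tgt in self.region_labels
            if src != tgt
        ]

    def index(self, label: str) -> int:
        try:
            return self.region_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown region label: {label!r}") from None


def connection_name(source: str, target: str) -> str:
    """Canonical string form of a directed connection."""
    return f"{source}->{target}"


def parse_connection(name: str) -> tuple[str, str]:
    source, sep, target = name.partition("->")
    if not sep or not source or not target:
        raise ValueError(f"not a connection name: {name!r}")
    return source, target
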