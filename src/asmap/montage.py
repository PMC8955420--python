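"""Channel ordering and electrode pair lists for asymmetry features.

A montage fixes three things the feature code depends on: the row/column
order of the asymmetry tensor, the left-right homologous pairs (DASM and
RASM), and the frontal-posterior pairs (DCAU). Two defaults ship as
packaged YAML: ``seed62`` (62 channels, 27 hemispheric and 23
frontal-posterior pairs) and ``deap32`` (32 channels). They are data, not
code — any montage file with the same keys loads the same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from asmap.errors import ValidationError

__all__ = ["Montage", "load_montage", "packaged_montage", "PACKAGED_MONTAGES"]

PACKAGED_MONTAGES = ("seed62", "deap32")


@dataclass(frozen=True)
class Montage:
    """Channel order plus hemispheric and frontal-posterior pair lists."""

    channel_order: tuple[str, ...]
    hemispheric_pairs: tuple[tuple[str, str], ...]
    frontal_posterior_pairs: tuple[tuple[str, str], ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        if len(set(self.channel_order)) != len(self.channel_order):
            raise ValidationError("montage channel_order contains duplicate names")
        known = set(self.channel_order)
        for kind, pairs in (
            ("hemispheric", self.hemispheric_pairs),
            ("frontal_posterior", self.frontal_posterior_pairs),
        ):
            seen: set[tuple[str, str]] = set()
            for a, b in pairs:
                if a == b:
                    raise ValidationError(f"{kind} pair ({a!r}, {b!r}) repeats one channel")
                for name in (a, b):
                    if name not in known:
                        raise ValidationError(
                            f"{kind} pair references unknown channel {name!r}"
                        )
                if (a, b) in seen:
                    raise ValidationError(f"duplicate {kind} pair ({a!r}, {b!r})")
                seen.add((a, b))

    @property
    def n_channels(self) -> int:
        return len(self.channel_order)

    def index(self, name: str) -> int:
        try:
            return self.channel_order.index(name)
        except ValueError:
            raise ValidationError(f"unknown channel {name!r} in montage {self.name!r}") from None

    def pair_indices(self, kind: str) -> list[tuple[int, int]]:
        """Integer index pairs for ``kind`` in {'hemispheric', 'frontal_posterior'}."""
        pairs = {
            "hemispheric": self.hemispheric_pairs,
            "frontal_posterior": self.frontal_posterior_pairs,
        }.get(kind)
        if pairs is None:
            raise ValidationError(f"unknown pair kind {kind!r}")
        return [(self.index(a), self.index(b)) for a, b in pairs]


def _parse_montage(doc: dict, name: str) -> Montage:
    for key in ("channel_order", "hemispheric_pairs", "frontal_posterior_pairs"):
        if key not in doc:
            raise ValidationError(f"montage config missing key {key!r}")
    return Montage(
        channel_order=tuple(str(c) for c in doc["channel_order"]),
        hemispheric_pairs=tuple((str(a), str(b)) for a, b in doc["hemispheric_pairs"]),
        frontal_posterior_pairs=tuple(
            (str(a), str(b)) for a, b in doc["frontal_posterior_pairs"]
        ),
        name=str(doc.get("name", name)),
    )


def load_montage(config_path: str | Path) -> Montage:
    """Load a montage from a YAML config file."""
    path = Path(config_path)
    with open(path, "r") as f:
        doc = yaml.safe_load(f)
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: montage config must be a mapping")
    return _parse_montage(doc, name=path.stem)


def packaged_montage(name: str) -> Montage:
    """Load one of the packaged defaults by name ('seed62' or 'deap32')."""
    if name not in PACKAGED_MONTAGES:
        raise ValidationError(f"no packaged montage {name!r}; choose from {PACKAGED_MONTAGES}")
    text = resources.files("asmap.data").joinpath(f"{name}.yaml").read_text()
    return _parse_montage(yaml.safe_load(text), name=name)
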