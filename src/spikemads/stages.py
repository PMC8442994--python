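"""Waddington developmental stage grid for cereal inflorescence time courses.

The Waddington scale indexes cereal inflorescence development from the
floral transition (W1) to anthesis (W10); W10.5 denotes a sample taken
three days after pollination. The default grid holds the eleven stages
sampled in a typical barley spike time course.
"""

from __future__ import annotations

from dataclasses import dataclass, field


DEFAULT_STAGE_LABELS = (
    "W1", "W1.5", "W2", "W2.5", "W3.5", "W4", "W4.5", "W6.5", "W8.5",
    "W9.5", "W10.5",
)

ORGANS = ("lemma", "palea", "lodicule", "stamen", "carpel")

#: organ -> floral whorl number (lemma/palea are both whorl-1 organs)
ORGAN_WHORL = {"lemma": 1, "palea": 1, "lodicule": 2, "stamen": 3, "carpel": 4}


def _label_to_value(label: str) -> float:
    if not label.startswith("W"):
        raise ValueError(f"stage label {label!r} does not look like a Waddington stage")
    return float(label[1:])


@dataclass(frozen=True)
class StageGrid:
    """Ordered Waddington stages with their numeric values.

    Parameters
    ----------
    labels : tuple of str
        Stage identifiers such as ``"W3.5"``.
    values : tuple of float
        Matching numeric stage values; must be strictly increasing.
    """

    labels: tuple[str, ...] = DEFAULT_STAGE_LABELS
    values: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.values is None:
            object.__setattr__(
                self, "values", tuple(_label_to_value(l) for l in self.labels)
            )
        if len(self.labels) != len(self.values):
            raise ValueError("labels and values must have equal length")
        if any(b <= a for a, b in zip(self.values, self.values[1:])):
            raise ValueError("stage values must be strictly increasing")

    def __len__(self) -> int:
        return len(self.labels)

    def value_of(self, label: str) -> float:
        try:
            return self.values[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"unknown stage label {label!r}") from None


DEFAULT_GRID = StageGrid()
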