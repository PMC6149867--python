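"""Sample sheets: ordered sample identifiers with binary sex labels."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from dioica.errors import InputError

MALE = "M"
FEMALE = "F"


@dataclass(frozen=True)
class SampleDesign:
    """Ordered samples and their sex labels for a two-sex comparison.

    Parameters
    ----------
    samples :
        Sample identifiers in the column order of the count matrix.
    sex :
        Mapping from sample id to ``"M"`` or ``"F"``.
    """

    samples: tuple[str, ...]
    sex: dict[str, str] = field(hash=False)

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise InputError("duplicate sample ids in design")
        missing = [s for s in self.samples if s not in self.sex]
        if missing:
            raise InputError(f"samples without a sex label: {missing}")
        bad = {s: v for s, v in self.sex.items() if v not in (MALE, FEMALE)}
        if bad:
            raise InputError(f"sex labels must be 'M' or 'F', got {bad}")
        if not self.males or not self.females:
            raise InputError("design requires at least one sample of each sex")

    @property
    def males(self) -> list[str]:
        return [s for s in self.samples if self.sex[s] == MALE]

    @property
    def females(self) -> list[str]:
        return [s for s in self.samples if self.sex[s] == FEMALE]

    def swapped(self) -> "SampleDesign":
        """Return a design with every sex label flipped (M<->F)."""
        flipped = {s: (FEMALE if v == MALE else MALE) for s, v in self.sex.items()}
        return SampleDesign(self.samples, flipped)

    def require_replicates(self, n: int = 2) -> None:
        """Raise unless both sexes have at least *n* replicates."""
        if len(self.males) < n or len(self.females) < n:
            raise InputError(
                f"need >= {n} replicates per sex, got "
                f"{len(self.males)} male / {len(self.females)} female"
            )

    @classmethod
    def from_lists(cls, males: list[str], females: list[str]) -> "SampleDesign":
        sex = {s: MALE for s in males} | {s: FEMALE for s in females}
        return cls(tuple(males) + tuple(females), sex)

    @classmethod
    def from_table(cls, path: str | Path) -> "SampleDesign":
        """Read a two-column sample sheet TSV (sample_id, sex)."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        cols = {c.lower(): c for c in df.columns}
        if "sample_id" not in cols or "sex" not in cols:
            raise InputError(
                f"sample sheet {path} must have columns sample_id and sex"
            )
        ids = df[cols["sample_id"]].tolist()
        sexes = df[cols["sex"]].tolist()
        return cls(tuple(ids), dict(zip(ids, sexes)))

    def to_table(self, path: str | Path) -> None:
        pd.DataFrame(
            {"sample_id": list(self.samples), "sex": [self.sex[s] for s in self.samples]}
        ).to_csv(path, sep="\t", index=False)
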