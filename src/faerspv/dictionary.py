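"""A minimal PT -> SOC mapping.

MedDRA itself is licensed, so the pipeline consumes a user-supplied
two-column table mapping each preferred term (PT) to exactly one system
organ class (SOC).  The same "$" dialect as the report tables is used.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable

from .io import DELIMITER

UNMAPPED_SOC = "UNMAPPED"


class MiniDictionary:
    """PT -> SOC mapping where every PT belongs to exactly one SOC."""

    def __init__(self, pt_to_soc: Dict[str, str]):
        self._map = {self._norm(pt): soc for pt, soc in pt_to_soc.items()}

    @staticmethod
    def _norm(term: str) -> str:
        return term.strip().casefold()

    def soc_of(self, pt: str) -> str:
        return self._map.get(self._norm(pt), UNMAPPED_SOC)

    def __contains__(self, pt: str) -> bool:
        return self._norm(pt) in self._map

    def __len__(self) -> int:
        return len(self._map)

    @property
    def pts(self) -> tuple:
        return tuple(sorted(self._map))

    @property
    def socs(self) -> tuple:
        return tuple(sorted(set(self._map.values())))

    def pts_in_soc(self, soc: str) -> tuple:
        return tuple(sorted(pt for pt, s in self._map.items() if s == soc))

    def save(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"PT{DELIMITER}SOC\n")
            for pt in sorted(self._map):
                fh.write(f"{pt}{DELIMITER}{self._map[pt]}\n")

    @classmethod
    def load(cls, path: str | Path) -> "MiniDictionary":
        mapping: Dict[str, str] = {}
        with Path(path).open("r", encoding="utf-8") as fh:
            header = fh.readline()
            if not header or DELIMITER not in header:
                raise ValueError(f"{path}: not a two-column PT{DELIMITER}SOC table")
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                pt, soc = line.split(DELIMITER, 1)
                mapping[pt] = soc
        return cls(mapping)

    @classmethod
    def from_pairs(cls, pairs: Iterable) -> "MiniDictionary":
        return cls(dict(pairs))
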