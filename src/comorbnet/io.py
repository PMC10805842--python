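"""Readers and writers for the tabular formats the pipeline exchanges.

Everything on disk is plain TSV/CSV (pandas round-trips), GMT for pathway
collections and YAML for configuration. The LD panel is a sparse long-format
r² table; :class:`LDTable` wraps it with the lookup semantics the analysis
modules rely on (absent pair => unlinked, self => r²=1).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


class LDTable:
    """Sparse pairwise-r² lookup.

    Pairs absent from the table are treated as unlinked (r²=0); every SNP is
    in perfect LD with itself. Sparse panels conventionally omit zero pairs,
    so absence is information, not an error.
    """

    def __init__(self, pairs: pd.DataFrame):
        required = {"snp_a", "snp_b", "r2"}
        if not required.issubset(pairs.columns):
            raise ValueError(f"LD table needs columns {sorted(required)}")
        self._mates: dict[str, dict[str, float]] = {}
        for a, b, r2 in pairs[["snp_a", "snp_b", "r2"]].itertuples(index=False):
            if a == b:
                continue
            self._mates.setdefault(a, {})[b] = float(r2)
            self._mates.setdefault(b, {})[a] = float(r2)

    @classmethod
    def from_file(cls, path: str | Path) -> "LDTable":
        return cls(read_tsv(path))

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._mates.get(a, {}).get(b, 0.0)

    def mates(self, snp: str, r2_min: float = 0.0) -> dict[str, float]:
        """Partners of ``snp`` with r² >= ``r2_min`` (the SNP itself excluded)."""
        return {s: v for s, v in self._mates.get(snp, {}).items() if v >= r2_min}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        seen = set()
        for a, partners in self._mates.items():
            for b, r2 in partners.items():
                key = (min(a, b), max(a, b))
                if key in seen:
                    continue
                seen.add(key)
                rows.append((key[0], key[1], r2))
        return pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"])


def read_gmt(path: str | Path) -> dict[str, dict]:
    """Read a GMT pathway collection: one pathway per line, tab-separated
    ``id <tab> description <tab> gene1 <tab> gene2 ...``."""
    collections: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            collections[parts[0]] = {
                "name": parts[1],
                "genes": set(g for g in parts[2:] if g),
            }
    return collections


def write_gmt(collections: dict[str, dict], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for pid, entry in collections.items():
            genes = "\t".join(sorted(entry["genes"]))
            fh.write(f"{pid}\t{entry.get('name', pid)}\t{genes}\n")
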