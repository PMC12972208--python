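"""Gene signature containers and readers (GMT and plain gene lists)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

__all__ = ["GeneSignature", "load_signature", "read_gmt", "match_signature"]


@dataclass(frozen=True)
class GeneSignature:
    """Named, ordered, de-duplicated list of gene symbols."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has an empty gene list")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} contains duplicate symbols")

    def __len__(self) -> int:
        return len(self.genes)


def _dedup(symbols) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for s in symbols:
        s = s.strip()
        if s and s not in seen:
            seen[s] = None
    return tuple(seen)


def read_gmt(path: str | Path) -> list[GeneSignature]:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> gene2 ...

    The description field is ignored.  Malformed lines (fewer than three
    fields) raise with the offending line number.
    """
    sigs: list[GeneSignature] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line {lineno}: expected >=3 tab-separated fields")
        name, _desc, *genes = fields
        symbols = _dedup(genes)
        if not symbols:
            raise ValueError(f"GMT line {lineno}: signature {name!r} has no genes")
        sigs.append(GeneSignature(name, symbols))
    return sigs


def load_signature(path: str | Path, format: str | None = None) -> GeneSignature:
    """Load one signature from a GMT file (its first line) or a one-symbol-
    per-line list file (named after the file stem).

    The format is inferred from the ``.gmt`` extension when not given.
    """
    path = Path(path)
    if format is None:
        format = "gmt" if path.suffix.lower() == ".gmt" else "list"
    if format == "gmt":
        sigs = read_gmt(path)
        return sigs[0]
    if format == "list":
        symbols = _dedup(path.read_text().splitlines())
        if not symbols:
            raise ValueError(f"signature file {path} contains no gene symbols")
        return GeneSignature(path.stem, symbols)
    raise ValueError(f"unknown signature format {format!r}")


def match_signature(sig: GeneSignature, features) -> tuple[list[str], list[str]]:
    """Split signature genes into (matched, missing) against ``features``.

    Matching is case-sensitive exact symbol comparison; the signature's
    order is preserved in both lists.  Zero matches is an error — scoring a
    signature with no measured genes is meaningless.
    """
    available = set(features)
    matched = [g for g in sig.genes if g in available]
    missing = [g for g in sig.genes if g not in available]
    if not matched:
        raise ValueError(f"no gene of signature {sig.name!r} is present in the matrix")
    return matched, missing
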