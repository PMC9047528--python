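"""Reaction dataset I/O: TSV reading/writing, multi-product splitting, splits.

The on-disk dialect is a UTF-8 TSV with header columns ``class``,
``reactants``, ``product`` (plus an optional leading ``id``); molecules
inside a field are '.'-separated.  Raw SMILES text is preserved verbatim at
read time — no canonicalization happens here, so the evaluation layer can
decide its own normalization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path


class ReactionParseError(ValueError):
    """A malformed dataset line; the message names the position."""


@dataclass(frozen=True)
class ReactionRecord:
    """One single-product reaction example."""

    record_id: str
    class_id: int
    reactants: tuple[str, ...]
    product: str

    def __post_init__(self):
        if "." in self.product:
            raise ReactionParseError(
                f"record {self.record_id}: multi-product record, run split_multiproduct first"
            )
        if not self.product:
            raise ReactionParseError(f"record {self.record_id}: empty product")
        if not self.reactants or any(not r for r in self.reactants):
            raise ReactionParseError(f"record {self.record_id}: empty reactant field")

    @property
    def reactants_str(self) -> str:
        return ".".join(self.reactants)


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test partition of a record list."""

    train: list[ReactionRecord]
    validation: list[ReactionRecord]
    test: list[ReactionRecord]
    seed: int
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)

    def __post_init__(self):
        ids = [r.record_id for part in (self.train, self.validation, self.test) for r in part]
        if len(ids) != len(set(ids)):
            raise ValueError("splits must be disjoint by record_id")

    @property
    def all_records(self) -> list[ReactionRecord]:
        return self.train + self.validation + self.test


def _parse_line(fields: dict[str, str], line_no: int, record_id: str | None,
                class_ids: set[int] | None) -> ReactionRecord:
    rid = record_id or fields.get("id") or f"L{line_no}"
    try:
        class_id = int(fields["class"])
    except ValueError:
        raise ReactionParseError(f"line {line_no}: non-integer class {fields['class']!r}")
    if class_ids is not None and class_id not in class_ids:
        raise ReactionParseError(f"line {line_no}: class {class_id} outside declared set")
    reactants = fields["reactants"].split(".") if fields["reactants"] else []
    if not reactants or any(not r for r in reactants):
        raise ReactionParseError(f"line {line_no}: empty reactants field")
    product = fields["product"]
    if not product:
        raise ReactionParseError(f"line {line_no}: empty product field")
    if "." in product:
        raise ReactionParseError(
            f"line {line_no}: multi-product record, run split_multiproduct first"
        )
    return ReactionRecord(rid, class_id, tuple(reactants), product)


REQUIRED_COLUMNS = ("class", "reactants", "product")


def read_reactions(path, class_ids: set[int] | None = None) -> list[ReactionRecord]:
    """Read a reaction TSV; malformed lines raise errors naming the line."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ReactionParseError(f"{path}: empty file (header expected)")
    header = lines[0].split("\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in header]
    if missing:
        raise ReactionParseError(f"{path}: missing column(s) {missing}")
    records = []
    for line_no, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        cells = raw.split("\t")
        if len(cells) != len(header):
            raise ReactionParseError(
                f"line {line_no}: {len(cells)} fields, header has {len(header)}"
            )
        records.append(_parse_line(dict(zip(header, cells)), line_no, None, class_ids))
    return records


def write_reactions(records: list[ReactionRecord], path) -> None:
    """Write records in canonical column order (id, class, reactants, product)."""
    lines = ["id\tclass\treactants\tproduct"]
    for r in records:
        lines.append(f"{r.record_id}\t{r.class_id}\t{r.reactants_str}\t{r.product}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def split_multiproduct(class_id: int, reactants: list[str], products: str,
                       record_id: str = "R") -> list[ReactionRecord]:
    """Expand a multi-product reaction into one record per product molecule.

    The reactant list is duplicated verbatim into each record and the product
    order is preserved; the total record count equals the number of
    '.'-separated product tokens.
    """
    if not products:
        raise ReactionParseError("empty products string")
    parts = products.split(".")
    if any(not p for p in parts):
        raise ReactionParseError(f"empty product token in {products!r}")
    suffix = [""] if len(parts) == 1 else [f".{i}" for i in range(1, len(parts) + 1)]
    return [
        ReactionRecord(f"{record_id}{sfx}", class_id, tuple(reactants), p)
        for p, sfx in zip(parts, suffix)
    ]


def _fisher_yates(n: int, seed: int) -> list[int]:
    """Seeded Fisher-Yates permutation; fixed algorithm so splits are portable."""
    import numpy as np

    rng = np.random.default_rng(seed)
    idx = list(range(n))
    for i in range(n - 1, 0, -1):
        j = int(rng.integers(0, i + 1))
        idx[i], idx[j] = idx[j], idx[i]
    return idx


def deduplicate_records(records: list[ReactionRecord]) -> list[ReactionRecord]:
    """Drop records repeating an earlier (class, reactants, product) triple."""
    seen: set[tuple] = set()
    out = []
    for r in records:
        key = (r.class_id, r.reactants, r.product)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def make_splits(records: list[ReactionRecord],
                fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                seed: int = 0,
                deduplicate: bool = False) -> DatasetSplit:
    """Shuffle deterministically and partition by floor-based sizes.

    Validation and test sizes are floors of their fractions; the remainder
    goes to train, so the three parts always partition the input.  Duplicate
    reactions are kept unless `deduplicate` is set — identical reactions can
    then land in different splits, which is the historical benchmark
    behavior.
    """
    if deduplicate:
        records = deduplicate_records(records)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be non-negative")
    n = len(records)
    n_parts = sum(1 for f in fractions if f > 0)
    if n < n_parts:
        raise ValueError(f"{n} records cannot fill {n_parts} non-empty split parts")
    order = _fisher_yates(n, seed)
    shuffled = [records[i] for i in order]
    n_val = int(n * fractions[1])
    n_test = int(n * fractions[2])
    n_train = n - n_val - n_test
    return DatasetSplit(
        train=shuffled[:n_train],
        validation=shuffled[n_train : n_train + n_val],
        test=shuffled[n_train + n_val :],
        seed=seed,
        fractions=tuple(fractions),
    )


def write_splits(split: DatasetSplit, out_dir) -> None:
    """Three TSVs plus a JSON manifest (seed, fractions, counts)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, part in (("train", split.train), ("validation", split.validation),
                       ("test", split.test)):
        write_reactions(part, out / f"{name}.tsv")
    manifest = {
        "seed": split.seed,
        "fractions": list(split.fractions),
        "counts": {
            "train": len(split.train),
            "validation": len(split.validation),
            "test": len(split.test),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def read_splits(in_dir) -> DatasetSplit:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    return DatasetSplit(
        train=read_reactions(in_dir / "train.tsv"),
        validation=read_reactions(in_dir / "validation.tsv"),
        test=read_reactions(in_dir / "test.tsv"),
        seed=manifest["seed"],
        fractions=tuple(manifest["fractions"]),
    )
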