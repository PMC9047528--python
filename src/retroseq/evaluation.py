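"""Scoring and failure analysis for ranked retrosynthesis predictions.

Covers four layers of the evaluation story:

* **top-N exact match** — a record counts for top-N if its recorded reactant
  multiset (canonical forms, order-insensitive) appears among the N highest
  ranked predictions; also broken down per reaction class;
* **grammatical invalidity** — the fraction of rank-1 predictions that fail
  to parse as SMILES at all, overall and per class;
* **failure-mode categorization** — failed records tagged by substructure
  motifs empirically linked to hard cases: Boc / CF3 / tBu quaternary-carbon
  groups and fused / spiro / bridged ring systems;
* **annotation-corrected ("true") accuracy** — exact matches plus
  predictions judged chemically plausible by expert annotation, reported
  both as a count-based fraction and as the sum of the two independently
  rounded percentage rates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem

from .lang import is_valid_smiles, reactant_set_match

PLAUSIBLE_TYPES = (
    "oxidation",
    "protection",
    "hydrolysis",
    "cc_coupling",
    "sn2",
    "reduction",
    "condensation",
    "other",
)

RING_CLASSES = ("acyclic", "simple-ring", "fused", "spiro", "bridged")

#: Versioned substructure registry for failure categorization.  The motifs
#: are named in the field's failure analyses but no published SMARTS exists,
#: so the patterns are defined (and versioned) here.  Boc takes precedence
#: over tBu: a tert-butyl carbon inside a Boc match is not counted again.
SUBSTRUCTURE_REGISTRY = {
    "version": 1,
    "patterns": {
        "R-Boc": "[CH3]C([CH3])([CH3])OC(=O)[#7]",
        "R-CF3": "[CX4](F)(F)F",
        "R-tBu": "[CH3]C([CH3])([CH3])[!F]",
    },
    "tbu_excluded_by": "R-Boc",
}


@dataclass(frozen=True)
class PlausibilityAnnotation:
    """An expert judgment that a non-matching prediction is chemically sound."""

    record_id: str
    plausible: bool
    reaction_type: str = "other"

    def __post_init__(self):
        if self.reaction_type not in PLAUSIBLE_TYPES:
            raise ValueError(
                f"unknown reaction type {self.reaction_type!r}; expected one of {PLAUSIBLE_TYPES}"
            )


@dataclass
class EvalReport:
    """All evaluation quantities for one prediction run."""

    n_test: int
    top_n: dict[int, float]
    per_class_top_n: dict[int, dict[int, float]]  # class -> {N: fraction}
    invalidity_rate: float
    per_class_invalidity: dict[int, float]
    failure_categories: dict[str, tuple[int, float]] = field(default_factory=dict)
    corrected: dict | None = None

    def to_dict(self) -> dict:
        return {
            "n_test": self.n_test,
            "top_n": {str(k): v for k, v in self.top_n.items()},
            "per_class_top_n": {
                str(c): {str(n): v for n, v in d.items()}
                for c, d in self.per_class_top_n.items()
            },
            "invalidity_rate": self.invalidity_rate,
            "per_class_invalidity": {str(c): v for c, v in self.per_class_invalidity.items()},
            "failure_categories": {k: list(v) for k, v in self.failure_categories.items()},
            "corrected": self.corrected,
        }


# ---------------------------------------------------------------------------
# accuracy


def _match_rank(predictions: list[str], truth: str) -> int | None:
    for rank, pred in enumerate(predictions, start=1):
        if reactant_set_match(pred, truth):
            return rank
    return None


def top_n_accuracy(
    predictions: dict[str, list[str]],
    truths: dict[str, str],
    ns: tuple[int, ...] = (1, 3, 5, 10),
) -> dict[int, float]:
    """Fraction of records whose truth matches some prediction of rank <= N."""
    if not predictions:
        raise ValueError("no predictions supplied")
    ranks = []
    for rid, preds in predictions.items():
        if rid not in truths:
            raise KeyError(f"no ground truth for record {rid}")
        if not preds:
            raise ValueError(f"record {rid} has no predictions")
        ranks.append(_match_rank(preds, truths[rid]))
    total = len(ranks)
    return {n: sum(1 for r in ranks if r is not None and r <= n) / total for n in ns}


def per_class_accuracy(
    predictions: dict[str, list[str]],
    truths: dict[str, str],
    class_ids: dict[str, int],
    n: int = 10,
    known_classes: set[int] | None = None,
) -> dict[int, float]:
    """Top-N accuracy restricted to each reaction class.

    Classes with zero records are absent from the result, not reported as 0.
    """
    by_class: dict[int, dict[str, list[str]]] = {}
    for rid in predictions:
        if rid not in class_ids:
            raise KeyError(f"no class id for record {rid}")
        cid = class_ids[rid]
        if known_classes is not None and cid not in known_classes:
            raise ValueError(f"unknown class id {cid} for record {rid}")
        by_class.setdefault(cid, {})[rid] = predictions[rid]
    return {
        cid: top_n_accuracy(preds, truths, ns=(n,))[n]
        for cid, preds in sorted(by_class.items())
    }


def invalidity_rate(
    rank1_predictions: dict[str, str],
    class_ids: dict[str, int] | None = None,
) -> tuple[float, dict[int, float]]:
    """Fraction of rank-1 predictions failing to parse, overall and per class."""
    if not rank1_predictions:
        return 0.0, {}
    invalid = {rid: not is_valid_smiles(p) for rid, p in rank1_predictions.items()}
    overall = sum(invalid.values()) / len(invalid)
    per_class: dict[int, float] = {}
    if class_ids is not None:
        counts: dict[int, list[int]] = {}
        for rid, bad in invalid.items():
            cid = class_ids[rid]
            counts.setdefault(cid, [0, 0])
            counts[cid][0] += bad
            counts[cid][1] += 1
        per_class = {c: b / n for c, (b, n) in sorted(counts.items())}
    return overall, per_class


# ---------------------------------------------------------------------------
# ring-system classification


def classify_ring_system(smiles: str) -> str:
    """Classify a molecule's ring system from its smallest set of smallest rings.

    Pairwise rule: two rings sharing exactly one atom -> spiro; exactly one
    bond (two adjacent atoms) -> fused; two or more atoms not all on one
    shared bond -> bridged.  Precedence bridged > spiro > fused when several
    relationships coexist.  Multi-fragment input is classified by its most
    complex fragment under the same precedence (with simple-ring > acyclic).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    rings = [frozenset(r) for r in Chem.GetSymmSSSR(mol)]
    if not rings:
        return "acyclic"
    bonds = {
        frozenset((b.GetBeginAtomIdx(), b.GetEndAtomIdx())) for b in mol.GetBonds()
    }
    found: set[str] = set()
    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            shared = rings[i] & rings[j]
            if len(shared) == 1:
                found.add("spiro")
            elif len(shared) == 2 and frozenset(shared) in bonds:
                found.add("fused")
            elif len(shared) >= 2:
                found.add("bridged")
    for cls in ("bridged", "spiro", "fused"):
        if cls in found:
            return cls
    return "simple-ring"


# ---------------------------------------------------------------------------
# failure categorization


def _motif_categories(smiles: str) -> set[str]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    pats = SUBSTRUCTURE_REGISTRY["patterns"]
    cats: set[str] = set()
    boc = Chem.MolFromSmarts(pats["R-Boc"])
    if boc is None:
        raise ValueError("malformed R-Boc pattern in registry")
    boc_matches = mol.GetSubstructMatches(boc)
    boc_atoms = {a for m in boc_matches for a in m}
    if boc_matches:
        cats.add("R-Boc")
    cf3 = Chem.MolFromSmarts(pats["R-CF3"])
    if mol.HasSubstructMatch(cf3):
        cats.add("R-CF3")
    tbu = Chem.MolFromSmarts(pats["R-tBu"])
    # Boc precedence: only count tBu matches outside every Boc match
    for m in mol.GetSubstructMatches(tbu):
        if not set(m[:4]) & boc_atoms:
            cats.add("R-tBu")
            break
    ring = classify_ring_system(smiles)
    if ring in ("fused", "spiro", "bridged"):
        cats.add(f"ring-{ring}")
    return cats


def categorize_failures(
    failed_records: list[tuple[str, str, str]],
) -> dict[str, tuple[int, float]]:
    """Tag failed records by substructure category.

    `failed_records` holds (record_id, truth_reactants, product) triples for
    records whose prediction failed; the truth molecules and the product are
    scanned for motifs.  Rates use the failed-record count as denominator,
    and the total row counts each record once per category it belongs to.
    """
    n_failed = len(failed_records)
    counts: Counter[str] = Counter()
    for _, truth, product in failed_records:
        cats: set[str] = set()
        for mol_smiles in truth.split(".") + [product]:
            cats |= _motif_categories(mol_smiles)
        counts.update(cats)
    out = {
        cat: (c, c / n_failed if n_failed else 0.0)
        for cat, c in sorted(counts.items())
    }
    total = sum(c for c, _ in out.values())
    out["total"] = (total, total / n_failed if n_failed else 0.0)
    return out


# ---------------------------------------------------------------------------
# annotation-corrected accuracy


def corrected_accuracy(
    n_test: int,
    exact_match_count: int,
    annotations: list[PlausibilityAnnotation],
    matched_ids: set[str] | None = None,
) -> dict:
    """Exact matches plus expert-plausible predictions.

    Returns count-based corrected fraction, a per-type breakdown with rates
    over the full test set, and the rate-sum percentage form (exact-match
    rate and total plausible rate rounded to one decimal independently, then
    summed) conventionally quoted for a "true" accuracy.
    """
    seen: set[str] = set()
    for a in annotations:
        if a.record_id in seen:
            raise ValueError(f"duplicate annotation for record {a.record_id}")
        seen.add(a.record_id)
        if matched_ids is not None and a.record_id in matched_ids:
            raise ValueError(
                f"record {a.record_id} already exact-matches; annotating it double-counts"
            )
    plausible = [a for a in annotations if a.plausible]
    by_type = Counter(a.reaction_type for a in plausible)
    n_plausible = len(plausible)
    corrected_count = exact_match_count + n_plausible
    exact_rate = exact_match_count / n_test
    plausible_rate = n_plausible / n_test
    breakdown = {
        t: {"count": c, "rate": c / n_test} for t, c in sorted(by_type.items())
    }
    breakdown["total"] = {"count": n_plausible, "rate": plausible_rate}
    return {
        "n_test": n_test,
        "exact_match_count": exact_match_count,
        "plausible_count": n_plausible,
        "corrected_count": corrected_count,
        "corrected_fraction": corrected_count / n_test,
        "exact_fraction": exact_rate,
        "rate_sum_pct": round(100 * exact_rate, 1) + round(100 * plausible_rate, 1),
        "breakdown": breakdown,
    }


def rate_sum_pct(exact_pct: float, plausible_pct: float) -> float:
    """The rounded rate-sum form of corrected accuracy, in percent."""
    return round(round(exact_pct, 1) + round(plausible_pct, 1), 1)


# ---------------------------------------------------------------------------
# orchestration


def evaluate_predictions(
    predictions: dict[str, list[str]],
    truths: dict[str, str],
    class_ids: dict[str, int],
    products: dict[str, str] | None = None,
    ns: tuple[int, ...] = (1, 3, 5, 10),
    annotations: list[PlausibilityAnnotation] | None = None,
) -> EvalReport:
    """Assemble the full report from ranked predictions and ground truth."""
    top = top_n_accuracy(predictions, truths, ns)
    per_class: dict[int, dict[int, float]] = {}
    for n in ns:
        for cid, acc in per_class_accuracy(predictions, truths, class_ids, n).items():
            per_class.setdefault(cid, {})[n] = acc
    rank1 = {rid: preds[0] for rid, preds in predictions.items()}
    inval, per_class_inval = invalidity_rate(rank1, class_ids)
    matched = {
        rid for rid, preds in predictions.items() if _match_rank(preds, truths[rid])
    }
    failed = [
        (rid, truths[rid], (products or {}).get(rid, truths[rid].split(".")[0]))
        for rid in predictions
        if rid not in matched
    ]
    failure_cats = categorize_failures(failed) if failed else {}
    corrected = None
    if annotations is not None:
        corrected = corrected_accuracy(
            len(predictions), len(matched), annotations, matched_ids=matched
        )
    return EvalReport(
        n_test=len(predictions),
        top_n=top,
        per_class_top_n=per_class,
        invalidity_rate=inval,
        per_class_invalidity=per_class_inval,
        failure_categories=failure_cats,
        corrected=corrected,
    )


# ---------------------------------------------------------------------------
# annotation I/O


def read_annotations(path) -> list[PlausibilityAnnotation]:
    """TSV with header: record_id, plausible (0/1/true/false), type."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    header = lines[0].split("\t")
    out = []
    for raw in lines[1:]:
        if not raw.strip():
            continue
        row = dict(zip(header, raw.split("\t")))
        out.append(
            PlausibilityAnnotation(
                record_id=row["record_id"],
                plausible=row["plausible"].lower() in ("1", "true", "yes"),
                reaction_type=row.get("type", "other"),
            )
        )
    return out
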