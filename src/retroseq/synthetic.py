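"""Template-based toy retrosynthesis datasets.

Each :class:`ReactionTemplate` is a pair of SMILES string patterns — a
product pattern and one or more reactant patterns — sharing named ``{slot}``
placeholders.  Instantiation is plain string substitution of fragments at
the marked attachment points, so every generated record is auditable by eye,
and the fragment alphabets are chosen so that any in-alphabet assignment
yields valid SMILES on both sides.

The five default templates mirror common medicinal-chemistry reaction
families (ester hydrolysis, SN2 etherification, Boc protection, amide
condensation, aryl-aryl coupling), which also gives the failure-analysis
code the protecting-group vocabulary it categorizes (Boc, tBu, CF3, rings).

Held-out splitting removes whole slot *combinations*, never individual
fragments, so a model scoring well on the test set must recombine fragments
it has seen in other contexts rather than memorize strings.
"""

from __future__ import annotations

import itertools
import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .data import DatasetSplit, ReactionRecord
from .lang import is_valid_smiles

_SLOT_RE = re.compile(r"\{(\w+)\}")


@dataclass(frozen=True)
class FragmentLibrary:
    """Named SMILES fragment alphabets with positional attachment conventions.

    A fragment list's name encodes where it may splice (its declaring
    templates place it consistently); validity of every splice is enforced
    by the generator tests rather than by graph chemistry.
    """

    fragments: dict[str, tuple[str, ...]]

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.fragments[name]

    def __contains__(self, name: str) -> bool:
        return name in self.fragments


@dataclass(frozen=True)
class ReactionTemplate:
    """A product pattern and reactant patterns over shared fragment slots."""

    template_id: str
    class_id: int
    product_pattern: str
    reactant_patterns: tuple[str, ...]
    slots: dict[str, str] = field(default_factory=dict)  # slot -> library list name

    def slot_names(self) -> list[str]:
        names = list(dict.fromkeys(_SLOT_RE.findall(self.product_pattern)))
        for pat in self.reactant_patterns:
            for s in _SLOT_RE.findall(pat):
                if s not in names:
                    names.append(s)
        return names


DEFAULT_LIBRARY = FragmentLibrary(
    {
        # acyl groups, attachment on the right (R-C(=O)-)
        "acyl": (
            "CC(=O)", "CCC(=O)", "CCCC(=O)", "CC(C)C(=O)", "CCCCC(=O)",
            "c1ccccc1C(=O)", "Cc1ccccc1C(=O)",
            "CC(C)(C)C(=O)", "CCOCC(=O)", "c1ccncc1C(=O)",
        ),
        # alkyl groups, attachment on the left (-O-R, -Br etc.)
        "alkyl": (
            "C", "CC", "CCC", "CCCC", "CC(C)", "CCCCC",
            "CC(C)C", "CCOC", "Cc1ccccc1", "CCc1ccccc1",
            "CCCCCC", "CC(C)CC",
        ),
        # phenol-type aryl cores, attachment on the left of the ring symbol
        "aryl": (
            "c1ccccc1", "c1ccc(C)cc1", "c1ccc(F)cc1", "c1ccc(Cl)cc1",
            "c1ccc(OC)cc1", "c1ccc(CC)cc1", "c1cccc(C)c1", "c1ccc(Br)cc1",
            "c1ccc(I)cc1", "c1cc(F)cc(C)c1", "c1ccc(CCC)cc1",
        ),
        # amine substituents usable both as N-branch "(frag)" and N-tail
        "amine_sub": (
            "C", "CC", "CCC", "CCCC", "CC(C)", "CCO",
            "Cc1ccccc1", "CCc1ccccc1", "CCOC", "CCCC(C)",
        ),
        # para substituents for biaryl partners, prefix position
        "aryl_prefix_sub": ("C", "CC", "F", "Cl", "OC", "FC(F)(F)", "CC(C)(C)", "OCC"),
        # para substituents for biaryl partners, in-parenthesis position
        "aryl_paren_sub": ("C", "CC", "F", "Cl", "OC", "C(F)(F)F", "C(C)(C)C", "CCO"),
    }
)


DEFAULT_TEMPLATES = (
    ReactionTemplate(
        # ester <-> acid/alcohol family; generated in the esterification
        # direction so the product determines both fragments (the reverse,
        # acid -> "which ester?", has no unique answer and would make the
        # recovery task ill-posed)
        "esterification", 1,
        "{acyl}O{alkyl}",
        ("{acyl}O", "O{alkyl}"),
        {"acyl": "acyl", "alkyl": "alkyl"},
    ),
    ReactionTemplate(
        "sn2_etherification", 2,
        "{alkyl}O{aryl}",
        ("O{aryl}", "{alkyl}Br"),
        {"alkyl": "alkyl", "aryl": "aryl"},
    ),
    ReactionTemplate(
        "boc_protection", 3,
        "CC(C)(C)OC(=O)N({t1}){t2}",
        ("N({t1}){t2}", "CC(C)(C)OC(=O)OC(C)(C)C"),
        {"t1": "amine_sub", "t2": "amine_sub"},
    ),
    ReactionTemplate(
        "amide_condensation", 4,
        "{acyl}N{tail}",
        ("{acyl}O", "N{tail}", "CCN=C=NCC"),
        {"acyl": "acyl", "tail": "amine_sub"},
    ),
    ReactionTemplate(
        "suzuki_coupling", 5,
        "{r1}c1ccc(-c2ccc({r2})cc2)cc1",
        ("{r1}c1ccc(Br)cc1", "OB(O)c1ccc({r2})cc1"),
        {"r1": "aryl_prefix_sub", "r2": "aryl_paren_sub"},
    ),
)


class TemplateError(ValueError):
    pass


def _substitute(pattern: str, assignment: dict[str, str]) -> str:
    return _SLOT_RE.sub(lambda m: assignment[m.group(1)], pattern)


def apply_template(
    template: ReactionTemplate,
    assignment: dict[str, str],
    library: FragmentLibrary = DEFAULT_LIBRARY,
    record_id: str | None = None,
) -> ReactionRecord:
    """Instantiate a template with one fragment per slot (deterministic)."""
    for slot in template.slot_names():
        if slot not in assignment:
            raise TemplateError(f"slot {slot!r} not assigned")
        list_name = template.slots[slot]
        if assignment[slot] not in library[list_name]:
            raise TemplateError(
                f"fragment {assignment[slot]!r} not in alphabet {list_name!r}"
            )
    product = _substitute(template.product_pattern, assignment)
    reactants = tuple(_substitute(p, assignment) for p in template.reactant_patterns)
    rid = record_id or template.template_id + ":" + "|".join(
        assignment[s] for s in template.slot_names()
    )
    return ReactionRecord(rid, template.class_id, reactants, product)


def _combinations(template: ReactionTemplate, library: FragmentLibrary):
    slots = template.slot_names()
    alphabets = [library[template.slots[s]] for s in slots]
    for combo in itertools.product(*alphabets):
        yield dict(zip(slots, combo))


def generate_dataset(
    templates=DEFAULT_TEMPLATES,
    library: FragmentLibrary = DEFAULT_LIBRARY,
    seed: int = 0,
    heldout_fraction: float = 0.1,
    validation_fraction: float | None = None,
) -> DatasetSplit:
    """Cross-product instantiation of all templates, split by slot combination.

    Per template, a `heldout_fraction` of its slot combinations becomes the
    test set (and the same-sized slice the validation set unless overridden);
    everything else trains.  Identical arguments give identical datasets.
    """
    if not templates:
        raise TemplateError("no templates supplied")
    if heldout_fraction >= 1:
        raise ValueError("heldout_fraction must be < 1")
    if validation_fraction is None:
        validation_fraction = heldout_fraction
    rng = np.random.default_rng(seed)
    train: list[ReactionRecord] = []
    val: list[ReactionRecord] = []
    test: list[ReactionRecord] = []
    for template in templates:
        combos = list(_combinations(template, library))
        order = rng.permutation(len(combos))
        n_test = int(len(combos) * heldout_fraction)
        n_val = int(len(combos) * validation_fraction)
        for pos, idx in enumerate(order):
            rec = apply_template(template, combos[idx], library)
            if pos < n_test:
                test.append(rec)
            elif pos < n_test + n_val:
                val.append(rec)
            else:
                train.append(rec)
    final = np.random.default_rng(seed + 1)
    for part in (train, val, test):
        perm = final.permutation(len(part))
        part[:] = [part[i] for i in perm]
    return DatasetSplit(train=train, validation=val, test=test, seed=seed)


def class_balance(split: DatasetSplit) -> dict[int, int]:
    """Record counts per reaction class over the full dataset."""
    return dict(sorted(Counter(r.class_id for r in split.all_records).items()))


# ---------------------------------------------------------------------------
# corruption


_RING_DIGIT = re.compile(r"(?<!%)\d")


def mutate_to_invalid(smiles: str, seed: int) -> str:
    """Corrupt a valid SMILES into one that fails to parse.

    One random edit per attempt — delete a ring-closure digit, unbalance a
    parenthesis, or truncate a bracket atom — retried up to 10 times, since a
    single edit occasionally leaves a parseable string.
    """
    if not is_valid_smiles(smiles):
        raise ValueError("mutate_to_invalid needs a valid input")
    rng = np.random.default_rng(seed)
    for _ in range(10):
        kind = rng.integers(0, 3)
        s = smiles
        if kind == 0:
            digits = [m.start() for m in _RING_DIGIT.finditer(s)]
            if digits:
                i = digits[int(rng.integers(0, len(digits)))]
                s = s[:i] + s[i + 1 :]
        elif kind == 1:
            i = int(rng.integers(0, len(s)))
            s = s[:i] + "(" + s[i:]
        else:
            if "]" in s:
                s = s.replace("]", "", 1)
            else:
                i = int(rng.integers(0, len(s)))
                s = s[:i] + "[" + s[i:]
        if s and not is_valid_smiles(s):
            return s
    raise ValueError(f"could not corrupt {smiles!r} after 10 attempts")
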