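"""SMILES tokenization, vocabularies, validity, canonicalization, matching.

Tokenization uses the atom-level regular expression conventional for
molecular translation work: bracket atoms ``[...]``, two-letter halogens
``Cl``/``Br``, two-digit ring closures ``%NN`` and every other SMILES symbol
become single tokens.  Chemistry (validity, canonical forms) is delegated to
RDKit; the match semantics for scoring predictions are defined here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # parse failures are an expected outcome here

PAD, BOS, EOS, UNK = "<pad>", "<bos>", "<eos>", "<unk>"
SPECIAL_TOKENS = (PAD, BOS, EOS, UNK)

# Atom-level SMILES token pattern (longest match first).
_TOKEN_RE = re.compile(
    r"(\[[^\]]*\]|Br|Cl|%\d{2}|[BCNOPSFIbcnops]|[0-9]|[=#\-\+\(\)/\\\.@:~\$\*])"
)


class TokenizationError(ValueError):
    pass


def tokenize_smiles(s: str) -> list[str]:
    """Split a SMILES string into atom-level tokens.

    Concatenating the returned tokens reproduces the input exactly.
    """
    if not s:
        raise TokenizationError("cannot tokenize an empty string")
    if s.count("[") != s.count("]"):
        raise TokenizationError(f"unbalanced brackets in {s!r}")
    tokens = _TOKEN_RE.findall(s)
    if "".join(tokens) != s:
        bad = _first_unmatched(s, tokens)
        raise TokenizationError(f"unrecognized character {bad!r} in {s!r}")
    return tokens


def _first_unmatched(s: str, tokens: list[str]) -> str:
    i = 0
    for tok in tokens:
        if not s.startswith(tok, i):
            break
        i += len(tok)
    return s[i] if i < len(s) else s[-1]


def detokenize(tokens: list[str]) -> str:
    return "".join(tokens)


def class_token(class_id: int) -> str:
    return f"<RX_{class_id}>"


@dataclass(frozen=True)
class Vocabulary:
    """Injective token -> consecutive-id map; PAD is always id 0."""

    token_to_id: dict[str, int]

    def __post_init__(self):
        ids = sorted(self.token_to_id.values())
        if ids != list(range(len(ids))):
            raise ValueError("vocabulary ids must be consecutive from 0")
        if self.token_to_id.get(PAD) != 0:
            raise ValueError("PAD must have id 0")

    def __len__(self) -> int:
        return len(self.token_to_id)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id

    @property
    def id_to_token(self) -> dict[int, str]:
        return {i: t for t, i in self.token_to_id.items()}

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def bos_id(self) -> int:
        return self.token_to_id[BOS]

    @property
    def eos_id(self) -> int:
        return self.token_to_id[EOS]

    def encode(self, tokens: list[str]) -> list[int]:
        unk = self.token_to_id[UNK]
        return [self.token_to_id.get(t, unk) for t in tokens]

    def decode(self, ids, strip_special: bool = True) -> list[str]:
        rev = self.id_to_token
        toks = [rev[int(i)] for i in ids]
        if strip_special:
            toks = [t for t in toks if t not in SPECIAL_TOKENS]
        return toks

    def save(self, path) -> None:
        lines = [f"{t}\t{i}" for t, i in sorted(self.token_to_id.items(), key=lambda kv: kv[1])]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path) -> "Vocabulary":
        mapping = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if line:
                tok, i = line.split("\t")
                mapping[tok] = int(i)
        return cls(mapping)


def write_token_lines(corpus: list[list[str]], path) -> None:
    """Persist a tokenized corpus as space-separated token lines."""
    Path(path).write_text("\n".join(" ".join(toks) for toks in corpus) + "\n",
                          encoding="utf-8")


def read_token_lines(path) -> list[list[str]]:
    return [line.split(" ") for line in
            Path(path).read_text(encoding="utf-8").splitlines() if line]


def build_vocabulary(corpus: list[list[str]], class_count: int = 0) -> Vocabulary:
    """Specials, then class tokens, then corpus tokens sorted lexicographically."""
    if not corpus:
        raise ValueError("corpus must be non-empty")
    seen: set[str] = set()
    for toks in corpus:
        seen.update(toks)
    ordered = list(SPECIAL_TOKENS)
    ordered += [class_token(c) for c in range(1, class_count + 1)]
    ordered += sorted(seen - set(ordered))
    return Vocabulary({t: i for i, t in enumerate(ordered)})


# ---------------------------------------------------------------------------
# chemistry


def is_valid_smiles(s: str) -> bool:
    """True iff `s` parses as one or more molecules.

    A dot-separated string is valid iff every component is; never raises.
    """
    if not isinstance(s, str) or not s.strip():
        return False
    try:
        return Chem.MolFromSmiles(s, sanitize=True) is not None
    except Exception:
        return False


class CanonicalizationError(ValueError):
    pass


def canonicalize(s: str) -> str:
    """Map a valid SMILES to RDKit's unique canonical form (idempotent)."""
    mol = Chem.MolFromSmiles(s) if isinstance(s, str) and s.strip() else None
    if mol is None:
        raise CanonicalizationError(f"not a valid SMILES: {s!r}")
    return Chem.MolToSmiles(mol)


def _canonical_multiset(s: str) -> tuple[str, ...] | None:
    if not is_valid_smiles(s):
        return None
    try:
        parts = [canonicalize(p) for p in s.split(".")]
    except CanonicalizationError:
        return None
    return tuple(sorted(parts))


def reactant_set_match(predicted: str, truth: str) -> bool:
    """Exact-match scoring: canonical molecule multisets must be equal.

    Order-insensitive but multiplicity-sensitive; an invalid string on either
    side never matches.
    """
    p = _canonical_multiset(predicted)
    t = _canonical_multiset(truth)
    return p is not None and t is not None and p == t
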