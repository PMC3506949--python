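"""Gene-protein-reaction (GPR) rule parsing and isozyme enumeration.

A GPR string is a boolean expression over gene identifiers using ``and``,
``or`` and parentheses.  OR branches denote alternative enzymes (isozymes),
AND denotes subunits of a complex that are jointly required.  Enumerating
the expression into disjunctive normal form yields one gene set per enzyme;
a reaction's flux capacity is then bounded by the summed contributions of
its enzymes, and a gene knockout disables exactly the enzymes whose gene
set contains a deleted gene.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field


class GPRParseError(ValueError):
    """Malformed GPR boolean expression; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")

# tokens that act as operators, case-insensitive; "&"/"|" accepted as
# synonyms because some SBML note fields use them
_AND_TOKENS = {"and", "&", "&&"}
_OR_TOKENS = {"or", "|", "||"}


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


@dataclass(frozen=True)
class GPRAssociation:
    """Isozyme list for one reaction.

    ``enzymes`` holds one frozenset of gene ids per isozyme, sorted
    lexicographically by their sorted gene tuples so the enumeration is
    order-stable.  ``zeroed`` marks enzymes whose contribution has been
    forced to zero by a gene knockout.
    """

    reaction_id: str
    enzymes: tuple[frozenset[str], ...]
    zeroed: tuple[bool, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.zeroed is None:
            object.__setattr__(self, "zeroed", tuple(False for _ in self.enzymes))
        if len(self.zeroed) != len(self.enzymes):
            raise ValueError("zeroed mask length mismatch")

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for enz in self.enzymes:
            out |= enz
        return frozenset(out)

    @property
    def n_enzymes(self) -> int:
        return len(self.enzymes)

    @property
    def active_enzymes(self) -> tuple[frozenset[str], ...]:
        return tuple(e for e, z in zip(self.enzymes, self.zeroed) if not z)

    def is_dead(self) -> bool:
        """True when every enzyme is zeroed (reaction cannot carry flux)."""
        return len(self.enzymes) > 0 and all(self.zeroed)

    def to_string(self) -> str:
        """Canonical serialization: DNF with sorted genes and enzymes."""
        parts = []
        for enz in self.enzymes:
            genes = sorted(enz)
            if len(genes) == 1:
                parts.append(genes[0])
            else:
                parts.append("(" + " and ".join(genes) + ")")
        return " or ".join(parts)


class _Parser:
    """Recursive-descent parser for GPR boolean expressions.

    Grammar (standard precedence, AND binds tighter than OR)::

        expr   := term ("or" term)*
        term   := factor ("and" factor)*
        factor := GENE | "(" expr ")"

    Each node is represented directly as a list of gene frozensets (its
    DNF), combined by union for OR and pairwise union-product for AND.
    """

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.idx = 0

    def _peek(self) -> tuple[str, int] | None:
        return self.tokens[self.idx] if self.idx < len(self.tokens) else None

    def _next(self) -> tuple[str, int]:
        tok = self._peek()
        if tok is None:
            raise GPRParseError("unexpected end of expression", len(self.text))
        self.idx += 1
        return tok

    def parse(self) -> list[frozenset[str]]:
        if not self.tokens:
            return []
        dnf = self._expr()
        if self._peek() is not None:
            tok, pos = self._peek()
            raise GPRParseError(f"unexpected token {tok!r}", pos)
        return dnf

    def _expr(self) -> list[frozenset[str]]:
        dnf = self._term()
        while True:
            tok = self._peek()
            if tok is not None and tok[0].lower() in _OR_TOKENS:
                self._next()
                dnf = dnf + self._term()
            else:
                return dnf

    def _term(self) -> list[frozenset[str]]:
        dnf = self._factor()
        while True:
            tok = self._peek()
            if tok is not None and tok[0].lower() in _AND_TOKENS:
                self._next()
                rhs = self._factor()
                dnf = [a | b for a in dnf for b in rhs]
            else:
                return dnf

    def _factor(self) -> list[frozenset[str]]:
        tok, pos = self._next()
        if tok == "(":
            inner = self._expr()
            closing = self._peek()
            if closing is None or closing[0] != ")":
                raise GPRParseError("unbalanced parenthesis", pos)
            self._next()
            return inner
        if tok == ")":
            raise GPRParseError("unexpected ')'", pos)
        low = tok.lower()
        if low in _AND_TOKENS or low in _OR_TOKENS:
            raise GPRParseError(f"operator {tok!r} where a gene was expected", pos)
        return [frozenset([tok])]


def _absorb(dnf: list[frozenset[str]]) -> list[frozenset[str]]:
    """Drop duplicate and non-minimal (superset) gene sets."""
    unique = sorted(set(dnf), key=lambda s: (len(s), sorted(s)))
    kept: list[frozenset[str]] = []
    for cand in unique:
        if not any(prev < cand for prev in kept):
            kept.append(cand)
    return kept


def parse_gpr(gpr: str, reaction_id: str = "") -> GPRAssociation:
    """Parse a GPR boolean string into its isozyme (DNF) enumeration.

    The result lists each enzyme as a minimal gene set: duplicates and
    supersets of another enzyme are absorbed, and enzymes are sorted
    lexicographically by their sorted gene ids, so parsing is idempotent on
    its own serialization.

    An empty (or whitespace-only) string yields zero enzymes, marking the
    reaction as having no GPR.

    Raises
    ------
    GPRParseError
        If the boolean expression is malformed; the error records the
        character position of the offending token.
    """
    dnf = _Parser(gpr.strip()).parse()
    enzymes = tuple(sorted(_absorb(dnf), key=lambda s: sorted(s)))
    return GPRAssociation(reaction_id=reaction_id, enzymes=enzymes)


def apply_knockout(
    associations: dict[str, GPRAssociation] | list[GPRAssociation],
    genes: set[str],
    known_genes: set[str] | None = None,
) -> dict[str, GPRAssociation] | list[GPRAssociation]:
    """Zero the contribution of every enzyme containing a knocked-out gene.

    ``known_genes``, when given, is the model's gene list; knockout genes
    outside it raise ``KeyError`` naming the offenders rather than being
    silently dropped.
    """
    genes = set(genes)
    if known_genes is not None:
        unknown = sorted(genes - set(known_genes))
        if unknown:
            raise KeyError(f"unknown knockout gene(s): {', '.join(unknown)}")

    def _ko(assoc: GPRAssociation) -> GPRAssociation:
        zeroed = tuple(
            z or bool(enz & genes) for enz, z in zip(assoc.enzymes, assoc.zeroed)
        )
        return GPRAssociation(assoc.reaction_id, assoc.enzymes, zeroed)

    if isinstance(associations, dict):
        return {rid: _ko(a) for rid, a in associations.items()}
    return [_ko(a) for a in associations]
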