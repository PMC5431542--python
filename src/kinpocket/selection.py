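"""A small atom-selection language.

The grammar supports the vocabulary needed to express the analysis
selections ("residues from the αC helix", "side chain atoms of R858",
"all heavy atom pairs", "water oxygens"):

.. code-block:: text

    expr      := term ("or" term)*
    term      := factor ("and" factor)*
    factor    := "not" factor | "(" expr ")" | primitive
    primitive := "resid"   range (range)*      # 758 | 758:770 | 758 to 770
               | "resname" WORD+
               | "name"    WORD+
               | "element" WORD+
               | "chain"   WORD+
               | "heavy" | "hydrogen" | "backbone" | "sidechain"
               | "water" | "all"

"backbone" means N/CA/C/O (+OXT) of non-water residues; "sidechain" is
every non-backbone atom of a non-water residue (hydrogens included — add
"and heavy" to drop them).  Residue numbering is taken verbatim from the
input file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .io import AtomSelection, Topology

__all__ = ["resolve_selection", "SelectionSyntaxError"]


class SelectionSyntaxError(ValueError):
    """Raised for a syntactically invalid selection, with the position."""

    def __init__(self, message: str, position: int, text: str):
        super().__init__(f"{message} at position {position} in {text!r}")
        self.position = position


_KEYWORDS = {
    "and", "or", "not", "resid", "resname", "name", "element", "chain",
    "heavy", "hydrogen", "backbone", "sidechain", "water", "all", "to",
}

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


@dataclass(frozen=True)
class _Token:
    text: str
    pos: int


def _tokenize(spec: str) -> list[_Token]:
    return [_Token(m.group(0), m.start()) for m in _TOKEN_RE.finditer(spec)]


class _Parser:
    def __init__(self, spec: str, topology: Topology):
        self.spec = spec
        self.top = topology
        self.tokens = _tokenize(spec)
        self.i = 0

    def _err(self, message: str, tok: _Token | None = None) -> SelectionSyntaxError:
        pos = tok.pos if tok is not None else len(self.spec)
        return SelectionSyntaxError(message, pos, self.spec)

    def peek(self) -> _Token | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> _Token:
        tok = self.peek()
        if tok is None:
            raise self._err("unexpected end of selection")
        self.i += 1
        return tok

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise self._err("empty selection")
        mask = self.expr()
        tok = self.peek()
        if tok is not None:
            raise self._err(f"unexpected token {tok.text!r}", tok)
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while (tok := self.peek()) is not None and tok.text.lower() == "or":
            self.next()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while (tok := self.peek()) is not None and tok.text.lower() == "and":
            self.next()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            raise self._err("unexpected end of selection")
        word = tok.text.lower()
        if word == "not":
            self.next()
            return ~self.factor()
        if tok.text == "(":
            self.next()
            mask = self.expr()
            closer = self.peek()
            if closer is None or closer.text != ")":
                raise self._err("unbalanced parenthesis", tok)
            self.next()
            return mask
        return self.primitive()

    def _values(self, keyword_tok: _Token) -> list[_Token]:
        values = []
        while (tok := self.peek()) is not None:
            if tok.text in "()" or tok.text.lower() in _KEYWORDS:
                break
            values.append(self.next())
        if not values:
            raise self._err(
                f"keyword {keyword_tok.text!r} requires at least one value",
                keyword_tok,
            )
        return values

    def _resid_ranges(self, keyword_tok: _Token) -> np.ndarray:
        mask = np.zeros(self.top.n_atoms, dtype=bool)
        saw_value = False
        while (tok := self.peek()) is not None:
            if tok.text in "()" or (
                tok.text.lower() in _KEYWORDS and tok.text.lower() != "to"
            ):
                break
            tok = self.next()
            text = tok.text
            if ":" in text:
                lo_s, _, hi_s = text.partition(":")
                lo, hi = self._int(lo_s, tok), self._int(hi_s, tok)
            else:
                lo = hi = self._int(text, tok)
                nxt = self.peek()
                if nxt is not None and nxt.text.lower() == "to":
                    self.next()
                    hi_tok = self.next()
                    hi = self._int(hi_tok.text, hi_tok)
            mask |= (self.top.res_ids >= lo) & (self.top.res_ids <= hi)
            saw_value = True
        if not saw_value:
            raise self._err("'resid' requires at least one residue number",
                            keyword_tok)
        return mask

    def _int(self, text: str, tok: _Token) -> int:
        try:
            return int(text)
        except ValueError:
            raise self._err(f"expected integer, got {text!r}", tok) from None

    def primitive(self) -> np.ndarray:
        tok = self.next()
        word = tok.text.lower()
        top = self.top
        if word == "resid":
            return self._resid_ranges(tok)
        if word == "resname":
            names = [t.text.upper() for t in self._values(tok)]
            return np.isin(top.res_names, names)
        if word == "name":
            names = [t.text.upper() for t in self._values(tok)]
            return np.isin(np.char.upper(top.atom_names), names)
        if word == "element":
            elems = [t.text.capitalize() for t in self._values(tok)]
            return np.isin(top.elements, elems)
        if word == "chain":
            chains = [t.text for t in self._values(tok)]
            return np.isin(top.chain_ids, chains)
        if word == "heavy":
            return top.elements != "H"
        if word == "hydrogen":
            return top.elements == "H"
        if word == "backbone":
            return top.is_backbone
        if word == "sidechain":
            return ~top.is_backbone & ~top.is_water
        if word == "water":
            return top.is_water
        if word == "all":
            return np.ones(top.n_atoms, dtype=bool)
        raise self._err(f"unknown selection keyword {tok.text!r}", tok)


def resolve_selection(
    topology: Topology, spec: str, label: str | None = None
) -> AtomSelection:
    """Resolve a selection expression to a deterministic, sorted index set.

    Empty selections are legal; the result's ``is_empty`` property flags
    them.  A syntactically invalid expression raises
    :class:`SelectionSyntaxError` carrying the character position.
    """
    mask = _Parser(spec, topology).parse()
    indices = np.flatnonzero(mask)
    return AtomSelection(label=label if label is not None else spec,
                         indices=indices)
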