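"""Residue selectors: name residue sets the way a protocol designer would.

Selectors resolve to residue-index sets against a conformation at broking
time, so protocol configuration can say ``chain(H)`` instead of hard-coding
residue numbers.  The expression language is deliberately small:

    chain(H)            all residues of the chain with ID H
    range(5, 20)        residues 5..20 inclusive
    and(X, Y) / or(X, Y) / not(X)    Boolean combinations
    all                 every residue (virtuals excluded)

Named selectors defined in a protocol config can be referenced by name.
"""

from __future__ import annotations

import re
from typing import Dict, FrozenSet, Optional

__all__ = ["Selector", "parse_selector", "resolve"]


class SelectorError(ValueError):
    pass


class Selector:
    """AST node; call resolve(conf) for the residue set."""

    def __init__(self, op: str, *args):
        self.op = op
        self.args = args

    def __repr__(self):
        return f"{self.op}({', '.join(map(repr, self.args))})"

    def resolve(self, conf, named: Optional[Dict[str, "Selector"]] = None) -> FrozenSet[int]:
        named = named or {}
        op = self.op
        if op == "chain":
            chain = conf.chain_by_id(self.args[0])
            return frozenset(chain.residues)
        if op == "range":
            lo, hi = self.args
            if not (1 <= lo <= hi <= conf.n_residues):
                raise SelectorError(
                    f"range({lo},{hi}) outside residues 1..{conf.n_residues}"
                )
            return frozenset(range(lo, hi + 1))
        if op == "all":
            return frozenset(int(r) for r in conf.real_residues)
        if op == "and":
            return self.args[0].resolve(conf, named) & self.args[1].resolve(conf, named)
        if op == "or":
            return self.args[0].resolve(conf, named) | self.args[1].resolve(conf, named)
        if op == "not":
            universe = frozenset(int(r) for r in conf.real_residues)
            return universe - self.args[0].resolve(conf, named)
        if op == "name":
            name = self.args[0]
            if name not in named:
                raise SelectorError(f"unknown selector name {name!r}")
            return named[name].resolve(conf, named)
        raise SelectorError(f"unknown selector op {op!r}")


_TOKEN = re.compile(r"\s*([A-Za-z_][A-Za-z0-9_]*|\d+|[(),])")


def parse_selector(text: str) -> Selector:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            raise SelectorError(f"cannot tokenize selector at: {text[pos:]!r}")
        tokens.append(m.group(1))
        pos = m.end()
    tokens.append(None)  # sentinel

    idx = 0

    def peek():
        return tokens[idx]

    def take(expected=None):
        nonlocal idx
        tok = tokens[idx]
        if expected is not None and tok != expected:
            raise SelectorError(f"expected {expected!r}, got {tok!r} in {text!r}")
        idx += 1
        return tok

    def expr() -> Selector:
        tok = take()
        if tok is None:
            raise SelectorError(f"unexpected end of selector {text!r}")
        if tok == "all":
            return Selector("all")
        if tok in ("and", "or"):
            take("(")
            a = expr()
            take(",")
            b = expr()
            take(")")
            return Selector(tok, a, b)
        if tok == "not":
            take("(")
            a = expr()
            take(")")
            return Selector("not", a)
        if tok == "chain":
            take("(")
            cid = take()
            take(")")
            return Selector("chain", cid)
        if tok == "range":
            take("(")
            lo = int(take())
            take(",")
            hi = int(take())
            take(")")
            return Selector("range", lo, hi)
        if tok.isidentifier():
            return Selector("name", tok)
        raise SelectorError(f"unexpected token {tok!r} in {text!r}")

    result = expr()
    if peek() is not None:
        raise SelectorError(f"trailing input in selector {text!r}")
    return result


def resolve(spec, conf, named: Optional[Dict[str, Selector]] = None) -> FrozenSet[int]:
    """Resolve a selector spec: Selector, expression string, int iterable, or None."""
    if named is None:
        # during broking the working conformation carries the protocol's
        # selector namespace
        named = getattr(conf, "named_selectors", None)
    if spec is None:
        return frozenset(int(r) for r in conf.real_residues)
    if isinstance(spec, Selector):
        return spec.resolve(conf, named)
    if isinstance(spec, str):
        return parse_selector(spec).resolve(conf, named)
    return frozenset(int(r) for r in spec)
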