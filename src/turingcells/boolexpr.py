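"""Boolean expressions over gate inputs A1..An.

Grammar (loosest to tightest binding): OR  ``+`` or ``|``; XOR ``^`` or
``⊕``; AND ``&``, ``*``, ``·`` or ``∙``; NOT prefix ``~`` or ``!``;
parentheses; constants ``0``/``1``; variables ``A1``, ``A2``, ...
XOR is the standard two-level form A1^A2 = A1&~A2 + ~A1&A2.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Sequence

__all__ = ["BooleanExpr", "truth_vector", "infer_expression"]

_TOKEN = re.compile(r"\s*(?:(A\d+)|([01])|([+|])|([\^⊕])|([&*·∙])|([~!])|([()]))")


class BoolParseError(ValueError):
    def __init__(self, text: str, pos: int, msg: str):
        super().__init__(f"{msg} at position {pos}: {text[:pos]}<HERE>{text[pos:]}")
        self.pos = pos


def _tokenize(text: str):
    pos = 0
    out = []
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            if text[pos:].strip() == "":
                break
            raise BoolParseError(text, pos, "unexpected character")
        var, const, or_, xor, and_, not_, par = m.groups()
        if var:
            out.append(("var", int(var[1:]), pos))
        elif const:
            out.append(("const", int(const), pos))
        elif or_:
            out.append(("or", None, pos))
        elif xor:
            out.append(("xor", None, pos))
        elif and_:
            out.append(("and", None, pos))
        elif not_:
            out.append(("not", None, pos))
        else:
            out.append((par, None, pos))
        pos = m.end()
    out.append(("end", None, len(text)))
    return out


def _parse(text: str):
    toks = _tokenize(text)
    idx = 0

    def peek():
        return toks[idx][0]

    def take(kind):
        nonlocal idx
        if toks[idx][0] != kind:
            raise BoolParseError(text, toks[idx][2], f"expected {kind}")
        tok = toks[idx]
        idx += 1
        return tok

    def atom():
        nonlocal idx
        kind, val, pos = toks[idx]
        if kind == "not":
            idx += 1
            return ("not", atom())
        if kind == "var":
            idx += 1
            return ("var", val)
        if kind == "const":
            idx += 1
            return ("const", val)
        if kind == "(":
            idx += 1
            node = or_expr()
            take(")")
            return node
        raise BoolParseError(text, pos, "expected variable, constant, '~' or '('")

    def and_expr():
        node = atom()
        while peek() == "and":
            take("and")
            node = ("and", node, atom())
        return node

    def xor_expr():
        node = and_expr()
        while peek() == "xor":
            take("xor")
            node = ("xor", node, and_expr())
        return node

    def or_expr():
        node = xor_expr()
        while peek() == "or":
            take("or")
            node = ("or", node, xor_expr())
        return node

    tree = or_expr()
    take("end")
    return tree


def _eval(node, bits) -> int:
    op = node[0]
    if op == "var":
        i = node[1]
        if i < 1 or i > len(bits):
            raise ValueError(f"expression uses A{i} but only {len(bits)} inputs given")
        return int(bits[i - 1])
    if op == "const":
        return node[1]
    if op == "not":
        return 1 - _eval(node[1], bits)
    a = _eval(node[1], bits)
    b = _eval(node[2], bits)
    if op == "and":
        return a & b
    if op == "or":
        return a | b
    return a ^ b


def _arity(node) -> int:
    op = node[0]
    if op == "var":
        return node[1]
    if op == "const":
        return 0
    return max(_arity(child) for child in node[1:])


@dataclass(frozen=True)
class BooleanExpr:
    """A parsed Boolean expression; call it on a bit sequence (A1..An)."""

    text: str

    def __post_init__(self):
        object.__setattr__(self, "_tree", _parse(self.text))

    @property
    def arity(self) -> int:
        return _arity(self._tree)

    def __call__(self, bits: Sequence[int] | str) -> int:
        if isinstance(bits, str):
            bits = [int(b) for b in bits]
        return _eval(self._tree, bits)


def truth_vector(expr: BooleanExpr, input_words: Sequence[str]) -> list[int]:
    """Evaluate an expression over a list of input words."""
    return [expr(w) for w in input_words]


def _minterms_to_sop(minterms: list[int], n: int) -> str:
    """Quine--McCluskey prime-implicant cover, rendered as a sum of products."""
    if not minterms:
        return "0"
    if len(minterms) == 2 ** n:
        return "1"
    terms = {(m, 0) for m in minterms}  # (value, dontcare mask)
    primes = set()
    while terms:
        merged = set()
        used = set()
        for a in terms:
            for b in terms:
                if a[1] != b[1]:
                    continue
                diff = a[0] ^ b[0]
                if diff and (diff & (diff - 1)) == 0:
                    merged.add((a[0] & b[0], a[1] | diff))
                    used.add(a)
                    used.add(b)
        primes |= terms - used
        terms = merged
    # greedy cover
    def covers(p, m):
        return (m & ~p[1]) == (p[0] & ~p[1])
    remaining = set(minterms)
    chosen = []
    while remaining:
        best = max(primes, key=lambda p: sum(covers(p, m) for m in remaining))
        chosen.append(best)
        remaining -= {m for m in remaining if covers(best, m)}
    parts = []
    for value, mask in sorted(chosen):
        lits = []
        for i in range(n):
            bit = 1 << (n - 1 - i)       # A1 is the most significant bit
            if mask & bit:
                continue
            lits.append(f"A{i + 1}" if value & bit else f"~A{i + 1}")
        parts.append("&".join(lits) if lits else "1")
    return " + ".join(parts)


def infer_expression(outputs: Sequence[int], input_words: Sequence[str]) -> BooleanExpr:
    """Minimal sum-of-products expression matching an output column."""
    n = len(input_words[0])
    minterms = [int(w, 2) for w, o in zip(input_words, outputs) if o]
    return BooleanExpr(_minterms_to_sop(minterms, n))


def all_input_words(n: int) -> list[str]:
    """All 2^n input words, in ascending binary order."""
    return ["".join(str(b) for b in bits)
            for bits in itertools.product((0, 1), repeat=n)]
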