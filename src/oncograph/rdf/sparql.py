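"""SPARQL 1.1 SELECT subset: basic graph patterns, DISTINCT, variables in
any triple position, and ``FILTER regex(str(?v), "pattern" [, "flags"])``.

No OPTIONAL/UNION/paths/aggregates; queries needing those belong in an
external triple store, which this package intentionally avoids.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Union

from ..errors import QuerySyntaxError
from .model import A, IRI, KnowledgeGraph, Literal, Term


@dataclass(frozen=True)
class Variable:
    name: str


PatternTerm = Union[Variable, IRI, Literal]


@dataclass(frozen=True)
class TriplePattern:
    s: PatternTerm
    p: PatternTerm
    o: PatternTerm


@dataclass(frozen=True)
class RegexFilter:
    var: Variable
    pattern: str
    flags: str = ""

    def accepts(self, term: Term) -> bool:
        flags = re.I if "i" in self.flags else 0
        return re.search(self.pattern, str(term), flags) is not None


@dataclass
class SelectQuery:
    variables: list  # [Variable] or [] meaning SELECT *
    distinct: bool
    patterns: list  # TriplePattern
    filters: list  # RegexFilter


_TOKEN = re.compile(r"""
    (?P<ws>\s+)
  | (?P<comment>\#[^\n]*)
  | (?P<iri><[^<>\s]*>)
  | (?P<string>"(?:[^"\\]|\\.)*"|'(?:[^'\\]|\\.)*')
  | (?P<var>\?[A-Za-z_][A-Za-z0-9_]*)
  | (?P<pname>[A-Za-z_][A-Za-z0-9_\-]*:[A-Za-z0-9_\-]*)
  | (?P<word>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<punct>[{}().,;*])
""", re.VERBOSE)

_KEYWORDS = {"prefix", "select", "distinct", "where", "filter", "regex",
             "str", "a"}


def _tokenize(text: str):
    tokens = []
    pos = 0
    line = 1
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            raise QuerySyntaxError(
                f"line {line}: unexpected character {text[pos]!r}")
        line += text[pos:m.end()].count("\n")
        kind = m.lastgroup
        if kind not in ("ws", "comment"):
            tokens.append((kind, m.group(), line))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.tokens = _tokenize(text)
        self.i = 0
        self.prefixes: dict[str, str] = {}

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        if tok is None:
            raise QuerySyntaxError("unexpected end of query")
        self.i += 1
        return tok

    def expect_word(self, word: str):
        tok = self.next()
        if tok[0] != "word" or tok[1].lower() != word:
            raise QuerySyntaxError(
                f"line {tok[2]}: expected {word.upper()}, found {tok[1]!r}")

    def expect_punct(self, ch: str):
        tok = self.next()
        if tok[0] != "punct" or tok[1] != ch:
            raise QuerySyntaxError(
                f"line {tok[2]}: expected {ch!r}, found {tok[1]!r}")

    def at_word(self, word: str) -> bool:
        tok = self.peek()
        return (tok is not None and tok[0] == "word"
                and tok[1].lower() == word)

    def parse(self) -> SelectQuery:
        while self.at_word("prefix"):
            self.next()
            tok = self.next()
            if tok[0] != "pname" or not tok[1].endswith(":"):
                # pname token includes the local part; prefix decls end in ':'
                if tok[0] != "pname":
                    raise QuerySyntaxError(
                        f"line {tok[2]}: expected prefix name")
            pfx = tok[1].split(":")[0]
            iri = self.next()
            if iri[0] != "iri":
                raise QuerySyntaxError(f"line {iri[2]}: expected IRI")
            self.prefixes[pfx] = iri[1][1:-1]

        self.expect_word("select")
        distinct = False
        if self.at_word("distinct"):
            self.next()
            distinct = True
        variables = []
        star = False
        while True:
            tok = self.peek()
            if tok is None:
                raise QuerySyntaxError("unexpected end after SELECT")
            if tok[0] == "var":
                variables.append(Variable(tok[1][1:]))
                self.next()
            elif tok[0] == "punct" and tok[1] == "*":
                star = True
                self.next()
            else:
                break
        if not variables and not star:
            raise QuerySyntaxError("SELECT needs variables or *")

        self.expect_word("where")
        self.expect_punct("{")
        patterns: list[TriplePattern] = []
        filters: list[RegexFilter] = []
        while True:
            tok = self.peek()
            if tok is None:
                raise QuerySyntaxError("unterminated WHERE block")
            if tok[0] == "punct" and tok[1] == "}":
                self.next()
                break
            if tok[0] == "punct" and tok[1] == ".":
                self.next()
                continue
            if self.at_word("filter"):
                filters.append(self._parse_filter())
                continue
            patterns.append(self._parse_triple())
        if self.peek() is not None:
            tok = self.peek()
            raise QuerySyntaxError(
                f"line {tok[2]}: trailing content {tok[1]!r}")
        return SelectQuery(variables, distinct, patterns, filters)

    def _term(self) -> PatternTerm:
        tok = self.next()
        kind, value, line = tok
        if kind == "var":
            return Variable(value[1:])
        if kind == "iri":
            return IRI(value[1:-1])
        if kind == "pname":
            pfx, _, local = value.partition(":")
            if pfx not in self.prefixes:
                raise QuerySyntaxError(f"line {line}: unknown prefix {pfx!r}")
            return IRI(self.prefixes[pfx] + local)
        if kind == "string":
            return Literal(value[1:-1])
        if kind == "word" and value.lower() == "a":
            return A
        raise QuerySyntaxError(f"line {line}: unexpected token {value!r}")

    def _parse_triple(self) -> TriplePattern:
        s = self._term()
        p = self._term()
        o = self._term()
        return TriplePattern(s, p, o)

    def _parse_filter(self) -> RegexFilter:
        self.expect_word("filter")
        self.expect_word("regex")
        self.expect_punct("(")
        self.expect_word("str")
        self.expect_punct("(")
        var_tok = self.next()
        if var_tok[0] != "var":
            raise QuerySyntaxError(
                f"line {var_tok[2]}: regex needs a variable")
        self.expect_punct(")")
        self.expect_punct(",")
        pat_tok = self.next()
        if pat_tok[0] != "string":
            raise QuerySyntaxError(
                f"line {pat_tok[2]}: regex needs a string pattern")
        flags = ""
        tok = self.peek()
        if tok is not None and tok[0] == "punct" and tok[1] == ",":
            self.next()
            flag_tok = self.next()
            if flag_tok[0] != "string":
                raise QuerySyntaxError(
                    f"line {flag_tok[2]}: regex flags must be a string")
            flags = flag_tok[1][1:-1]
        self.expect_punct(")")
        return RegexFilter(Variable(var_tok[1][1:]), pat_tok[1][1:-1], flags)


def parse_query(text: str) -> SelectQuery:
    return _Parser(text).parse()


def _substitute(term: PatternTerm, binding: dict):
    if isinstance(term, Variable):
        return binding.get(term.name)
    return term


def _evaluate_bgp(graph: KnowledgeGraph, patterns, filters):
    def relevant_filters(bound_vars):
        return [f for f in filters if f.var.name in bound_vars]

    def recurse(idx: int, binding: dict):
        if idx == len(patterns):
            yield dict(binding)
            return
        pat = patterns[idx]
        s = _substitute(pat.s, binding)
        p = _substitute(pat.p, binding)
        o = _substitute(pat.o, binding)
        if isinstance(s, Literal):
            return  # literal subjects never match
        for ts, tp, to in graph.match(
                s if isinstance(s, IRI) else None,
                p if isinstance(p, IRI) else None,
                o if o is not None else None):
            new = {}
            ok = True
            for patterm, value in ((pat.s, ts), (pat.p, tp), (pat.o, to)):
                if isinstance(patterm, Variable):
                    if patterm.name in binding:
                        if binding[patterm.name] != value:
                            ok = False
                            break
                    elif patterm.name in new:
                        if new[patterm.name] != value:
                            ok = False
                            break
                    else:
                        new[patterm.name] = value
                elif patterm != value:
                    # literal object compared by full term equality
                    if isinstance(patterm, Literal) and isinstance(
                            value, Literal):
                        if patterm.lexical != value.lexical:
                            ok = False
                            break
                    else:
                        ok = False
                        break
            if not ok:
                continue
            binding.update(new)
            if all(f.accepts(binding[f.var.name])
                   for f in relevant_filters(new)):
                yield from recurse(idx + 1, binding)
            for k in new:
                del binding[k]

    yield from recurse(0, {})


def run_query(graph: KnowledgeGraph, sparql: str):
    """Execute a SELECT query; returns (header, rows) where rows are tuples
    of string-rendered terms in SELECT order."""
    q = parse_query(sparql)
    bindings = list(_evaluate_bgp(graph, q.patterns, q.filters))
    # filters over variables never bound by any pattern reject everything
    for f in q.filters:
        bindings = [b for b in bindings
                    if f.var.name not in b or f.accepts(b[f.var.name])]
    if q.variables:
        header = [v.name for v in q.variables]
    else:
        seen = []
        for pat in q.patterns:
            for t in (pat.s, pat.p, pat.o):
                if isinstance(t, Variable) and t.name not in seen:
                    seen.append(t.name)
        header = seen
    rows = []
    for b in bindings:
        rows.append(tuple(str(b.get(name, "")) for name in header))
    if q.distinct:
        out, seen_rows = [], set()
        for r in rows:
            if r not in seen_rows:
                seen_rows.add(r)
                out.append(r)
        rows = out
    return header, rows
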