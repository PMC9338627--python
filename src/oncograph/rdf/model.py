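"""Minimal RDF data model: IRIs, literals, and a triple-set graph with
Turtle and N-Triples round-trip serialization.

The store is intentionally small: a frozen term model over a Python set of
triples, enough to materialize the schema graph and serve the SELECT query
subset in :mod:`oncograph.rdf.sparql` without external services.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

from ..errors import RDFParseError

RDF_TYPE = "http://www.w3.org/1999/02/22-rdf-syntax-ns#type"
XSD = "http://www.w3.org/2001/XMLSchema#"
XSD_DATE = XSD + "date"


@dataclass(frozen=True, order=True)
class IRI:
    value: str

    def __str__(self) -> str:
        return self.value

    def n3(self) -> str:
        return f"<{self.value}>"


@dataclass(frozen=True, order=True)
class Literal:
    lexical: str
    datatype: Optional[str] = None

    def __str__(self) -> str:
        return self.lexical

    def n3(self) -> str:
        out = '"' + _escape(self.lexical) + '"'
        if self.datatype:
            out += f"^^<{self.datatype}>"
        return out


Term = Union[IRI, Literal]
Triple = tuple[IRI, IRI, Term]

A = IRI(RDF_TYPE)


def _escape(s: str) -> str:
    return (s.replace("\\", "\\\\").replace('"', '\\"')
            .replace("\n", "\\n").replace("\r", "\\r").replace("\t", "\\t"))


_UNESCAPE = {
    "\\\\": "\\", '\\"': '"', "\\n": "\n", "\\r": "\r", "\\t": "\t",
}


def _unescape(s: str) -> str:
    out = []
    i = 0
    while i < len(s):
        if s[i] == "\\" and i + 1 < len(s):
            pair = s[i:i + 2]
            if pair in _UNESCAPE:
                out.append(_UNESCAPE[pair])
                i += 2
                continue
            if pair == "\\u" and i + 6 <= len(s):
                out.append(chr(int(s[i + 2:i + 6], 16)))
                i += 6
                continue
            if pair == "\\U" and i + 10 <= len(s):
                out.append(chr(int(s[i + 2:i + 10], 16)))
                i += 10
                continue
        out.append(s[i])
        i += 1
    return "".join(out)


class KnowledgeGraph:
    """A set of RDF triples under a base namespace."""

    def __init__(self, namespace: str = "http://example.org/oncograph/",
                 triples: Optional[Iterable[Triple]] = None):
        self.namespace = namespace
        self.triples: set[Triple] = set(triples or ())

    def add(self, s: IRI, p: IRI, o: Term) -> None:
        self.triples.add((s, p, o))

    def __len__(self) -> int:
        return len(self.triples)

    def __contains__(self, triple: Triple) -> bool:
        return triple in self.triples

    def __eq__(self, other) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return self.triples == other.triples

    def match(self, s: Optional[IRI] = None, p: Optional[IRI] = None,
              o: Optional[Term] = None):
        for ts, tp, to in self.triples:
            if ((s is None or ts == s) and (p is None or tp == p)
                    and (o is None or to == o)):
                yield ts, tp, to

    def subjects_of_type(self, class_iri: IRI):
        for s, _, _ in self.match(p=A, o=class_iri):
            yield s

    def type_of(self, subject: IRI) -> Optional[IRI]:
        for _, _, o in self.match(s=subject, p=A):
            if isinstance(o, IRI):
                return o
        return None

    # ---- serialization ----------------------------------------------------

    def serialize(self, path, fmt: Optional[str] = None) -> None:
        path = Path(path)
        fmt = fmt or _format_from_suffix(path)
        if fmt == "ntriples":
            text = self.to_ntriples()
        elif fmt == "turtle":
            text = self.to_turtle()
        else:
            raise ValueError(f"unknown RDF format {fmt!r}")
        path.write_text(text, encoding="utf-8")

    def to_ntriples(self) -> str:
        lines = [
            f"{s.n3()} {p.n3()} {o.n3()} ."
            for s, p, o in sorted(
                self.triples, key=lambda t: (t[0], t[1], t[2].n3()))
        ]
        return "\n".join(lines) + ("\n" if lines else "")

    def to_turtle(self) -> str:
        prefixes = {"og": self.namespace, "rdf": RDF_TYPE.rsplit("#", 1)[0] + "#",
                    "xsd": XSD}
        out = [f"@prefix {p}: <{ns}> ." for p, ns in prefixes.items()]
        out.append("")

        def term(t: Term) -> str:
            if isinstance(t, Literal):
                lit = '"' + _escape(t.lexical) + '"'
                if t.datatype:
                    return lit + "^^" + term(IRI(t.datatype))
                return lit
            if t == A:
                return "a"
            for p, ns in prefixes.items():
                if t.value.startswith(ns):
                    local = t.value[len(ns):]
                    if re.fullmatch(r"[A-Za-z_][A-Za-z0-9_\-]*", local):
                        return f"{p}:{local}"
            return t.n3()

        by_subject: dict[IRI, list] = {}
        for s, p, o in self.triples:
            by_subject.setdefault(s, []).append((p, o))
        for s in sorted(by_subject):
            pos = sorted(by_subject[s], key=lambda po: (po[0], po[1].n3()))
            lines = [f"{term(s)}"]
            for i, (p, o) in enumerate(pos):
                sep = " ;" if i < len(pos) - 1 else " ."
                lines.append(f"    {term(p)} {term(o)}{sep}")
            out.append("\n".join(lines))
        return "\n".join(out) + "\n"


def _format_from_suffix(path: Path) -> str:
    if path.suffix in (".nt", ".ntriples"):
        return "ntriples"
    if path.suffix in (".ttl", ".turtle"):
        return "turtle"
    raise ValueError(f"cannot infer RDF format from {path.name!r}")


def parse(path, fmt: Optional[str] = None,
          namespace: str = "http://example.org/oncograph/") -> KnowledgeGraph:
    path = Path(path)
    fmt = fmt or _format_from_suffix(path)
    text = path.read_text(encoding="utf-8")
    if fmt == "ntriples":
        triples = _parse_ntriples(text)
    elif fmt == "turtle":
        triples = _parse_turtle(text)
    else:
        raise ValueError(f"unknown RDF format {fmt!r}")
    return KnowledgeGraph(namespace=namespace, triples=triples)


_NT_LINE = re.compile(
    r"^<(?P<s>[^>]*)>\s+<(?P<p>[^>]*)>\s+"
    r"(?:<(?P<o_iri>[^>]*)>|\"(?P<o_lit>(?:[^\"\\]|\\.)*)\""
    r"(?:\^\^<(?P<dt>[^>]*)>)?)\s*\.\s*$")


def _parse_ntriples(text: str) -> set[Triple]:
    triples: set[Triple] = set()
    # split on "\n" only: splitlines() would also break on stray unicode
    # line separators that are legal inside literals
    for lineno, line in enumerate(text.split("\n"), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        m = _NT_LINE.match(stripped)
        if not m:
            raise RDFParseError(f"malformed N-Triples statement: {line!r}",
                                line=lineno)
        s = IRI(m.group("s"))
        p = IRI(m.group("p"))
        if m.group("o_iri") is not None:
            o: Term = IRI(m.group("o_iri"))
        else:
            o = Literal(_unescape(m.group("o_lit")), m.group("dt"))
        triples.add((s, p, o))
    return triples


# ---- Turtle subset parser --------------------------------------------------

_TOKEN = re.compile(r"""
    (?P<ws>\s+)
  | (?P<comment>\#[^\n]*)
  | (?P<prefix_decl>@prefix\b)
  | (?P<iri><[^<>\s]*>)
  | (?P<string>"(?:[^"\\]|\\.)*")
  | (?P<dtsep>\^\^)
  | (?P<pname>[A-Za-z_][A-Za-z0-9_\-]*?:[A-Za-z0-9_\-]*)
  | (?P<nsdecl>[A-Za-z_][A-Za-z0-9_\-]*:)
  | (?P<kw_a>\ba\b)
  | (?P<punct>[;,.])
""", re.VERBOSE)


def _tokenize_turtle(text: str):
    tokens = []
    pos = 0
    line = 1
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            raise RDFParseError(
                f"unexpected character {text[pos]!r}", line=line)
        line += text[pos:m.end()].count("\n")
        kind = m.lastgroup
        if kind not in ("ws", "comment"):
            tokens.append((kind, m.group(), line))
        pos = m.end()
    return tokens


def _parse_turtle(text: str) -> set[Triple]:
    tokens = _tokenize_turtle(text)
    prefixes: dict[str, str] = {}
    triples: set[Triple] = set()
    i = 0

    def expect(kind):
        nonlocal i
        if i >= len(tokens) or tokens[i][0] != kind:
            found = tokens[i] if i < len(tokens) else ("eof", "", -1)
            raise RDFParseError(
                f"expected {kind}, found {found[1]!r}", line=found[2])
        tok = tokens[i]
        i += 1
        return tok

    def term() -> Term:
        nonlocal i
        if i >= len(tokens):
            raise RDFParseError("unexpected end of input")
        kind, value, line = tokens[i]
        if kind == "iri":
            i += 1
            return IRI(value[1:-1])
        if kind in ("pname", "nsdecl"):
            i += 1
            pfx, _, local = value.partition(":")
            if pfx not in prefixes:
                raise RDFParseError(f"unknown prefix {pfx!r}", line=line)
            return IRI(prefixes[pfx] + local)
        if kind == "kw_a":
            i += 1
            return A
        if kind == "string":
            i += 1
            lex = _unescape(value[1:-1])
            dtype = None
            if i < len(tokens) and tokens[i][0] == "dtsep":
                i += 1
                dt_term = term()
                if not isinstance(dt_term, IRI):
                    raise RDFParseError("datatype must be an IRI", line=line)
                dtype = dt_term.value
            return Literal(lex, dtype)
        raise RDFParseError(f"unexpected token {value!r}", line=line)

    while i < len(tokens):
        kind, value, line = tokens[i]
        if kind == "prefix_decl":
            i += 1
            ns_tok = tokens[i] if i < len(tokens) else None
            if ns_tok is None or ns_tok[0] not in ("nsdecl", "pname"):
                raise RDFParseError("expected prefix name after @prefix",
                                    line=line)
            i += 1
            pfx = ns_tok[1].split(":")[0]
            iri_tok = expect("iri")
            prefixes[pfx] = iri_tok[1][1:-1]
            expect("punct")  # '.'
            continue
        subj = term()
        if not isinstance(subj, IRI):
            raise RDFParseError("subject must be an IRI", line=line)
        while True:
            pred = term()
            if not isinstance(pred, IRI):
                raise RDFParseError("predicate must be an IRI", line=line)
            while True:
                obj = term()
                triples.add((subj, pred, obj))
                if i < len(tokens) and tokens[i][1] == ",":
                    i += 1
                    continue
                break
            tok = expect("punct")
            if tok[1] == ".":
                break
            if tok[1] != ";":
                raise RDFParseError(
                    f"expected ';' or '.', found {tok[1]!r}", line=tok[2])
    return triples
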