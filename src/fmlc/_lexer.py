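"""Shared tokenizer for FML text and embedded FHIRPath expressions.

FML rules embed FHIRPath conditions inline (``where``/``check``/``evaluate``),
so both parsers run over one token stream: the expression parser simply stops
at tokens it cannot extend an expression with (``->``, ``;``, ``then``, ...).
"""
from __future__ import annotations

from dataclasses import dataclass

from .errors import ParseError

# multi-character symbols first (longest match wins)
_SYMBOLS = [
    "->", "==", "!=", "<=", ">=", "<<", ">>",
    ".", ",", ";", ":", "(", ")", "{", "}", "[", "]",
    "=", "<", ">", "+", "-", "*", "/", "&", "|", "%", "$",
]

_ESCAPES = {"n": "\n", "t": "\t", "r": "\r", "f": "\f",
            "\\": "\\", "'": "'", '"': '"', "`": "`"}


@dataclass(frozen=True)
class Token:
    kind: str  # IDENT NUMBER STRING DQSTRING DATE SYM EOF
    value: str
    line: int
    col: int

    def is_sym(self, *vals: str) -> bool:
        return self.kind == "SYM" and self.value in vals

    def is_ident(self, *vals: str) -> bool:
        return self.kind == "IDENT" and (not vals or self.value in vals)


def tokenize(text: str) -> list[Token]:
    tokens: list[Token] = []
    i, line, col = 0, 1, 1
    n = len(text)

    def bump(k: int):
        nonlocal i, line, col
        for _ in range(k):
            if i < n and text[i] == "\n":
                line += 1
                col = 1
            else:
                col += 1
            i += 1

    while i < n:
        c = text[i]
        if c in " \t\r\n":
            bump(1)
            continue
        if text.startswith("//", i):
            j = text.find("\n", i)
            bump((j if j != -1 else n) - i)
            continue
        if text.startswith("/*", i):
            j = text.find("*/", i)
            if j == -1:
                raise ParseError("unterminated block comment", line, col)
            bump(j + 2 - i)
            continue
        if c in "'\"":
            quote, sline, scol = c, line, col
            j = i + 1
            buf: list[str] = []
            while j < n and text[j] != quote:
                if text[j] == "\\":
                    if j + 1 >= n or text[j + 1] not in _ESCAPES:
                        raise ParseError(f"bad escape sequence", sline, scol)
                    buf.append(_ESCAPES[text[j + 1]])
                    j += 2
                elif text[j] == "\n":
                    raise ParseError("unterminated string literal", sline, scol)
                else:
                    buf.append(text[j])
                    j += 1
            if j >= n:
                raise ParseError("unterminated string literal", sline, scol)
            tokens.append(Token("STRING" if quote == "'" else "DQSTRING",
                                "".join(buf), sline, scol))
            bump(j + 1 - i)
            continue
        if c == "@":
            j = i + 1
            while j < n and (text[j].isdigit() or text[j] in "-T:+.Z"):
                j += 1
            tokens.append(Token("DATE", text[i + 1:j], line, col))
            bump(j - i)
            continue
        if c.isdigit():
            j = i
            while j < n and text[j].isdigit():
                j += 1
            if j < n and text[j] == "." and j + 1 < n and text[j + 1].isdigit():
                j += 1
                while j < n and text[j].isdigit():
                    j += 1
            tokens.append(Token("NUMBER", text[i:j], line, col))
            bump(j - i)
            continue
        if c.isalpha() or c == "_":
            j = i
            while j < n and (text[j].isalnum() or text[j] == "_"):
                j += 1
            tokens.append(Token("IDENT", text[i:j], line, col))
            bump(j - i)
            continue
        for sym in _SYMBOLS:
            if text.startswith(sym, i):
                tokens.append(Token("SYM", sym, line, col))
                bump(len(sym))
                break
        else:
            raise ParseError(f"unexpected character {c!r}", line, col)
    tokens.append(Token("EOF", "", line, col))
    return tokens


class TokenStream:
    def __init__(self, tokens: list[Token]):
        self.tokens = tokens
        self.pos = 0

    @property
    def cur(self) -> Token:
        return self.tokens[self.pos]

    def peek(self, k: int = 1) -> Token:
        return self.tokens[min(self.pos + k, len(self.tokens) - 1)]

    def advance(self) -> Token:
        t = self.cur
        if t.kind != "EOF":
            self.pos += 1
        return t

    def expect_sym(self, value: str) -> Token:
        t = self.cur
        if not t.is_sym(value):
            raise ParseError(f"expected {value!r}, found {t.value or t.kind!r}",
                             t.line, t.col)
        return self.advance()

    def expect_ident(self, *values: str) -> Token:
        t = self.cur
        if t.kind != "IDENT" or (values and t.value not in values):
            what = " or ".join(repr(v) for v in values) if values else "identifier"
            raise ParseError(f"expected {what}, found {t.value or t.kind!r}",
                             t.line, t.col)
        return self.advance()

    def error(self, message: str) -> ParseError:
        return ParseError(message, self.cur.line, self.cur.col)
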