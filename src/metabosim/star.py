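"""Minimal STAR (Self-defining Text Archive and Retrieval) reader/writer.

Implements the subset of STAR syntax used by NEF-style files: one
``data_`` block, ``save_`` frames holding ``_category.tag value`` pairs and
``loop_`` tables with explicit ``_category.column`` headers terminated by
``stop_``.  Values may be bare tokens, single- or double-quoted strings, or
semicolon-delimited multi-line text; ``.`` is the null value and ``#``
starts a comment.  This is deliberately small — enough to guarantee a
lossless round trip of the per-metabolite entry dialect — but the emitted
files are syntactically ordinary STAR and readable by any NEF/NMR-STAR
tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ParseError

__all__ = ["Loop", "Saveframe", "DataBlock", "parse", "serialize"]

NULL = "."


@dataclass
class Loop:
    """A STAR loop: column names (``_cat.col``) and rows of string values."""

    columns: list[str]
    rows: list[list[str | None]] = field(default_factory=list)

    @property
    def category(self) -> str:
        return self.columns[0].split(".")[0] if self.columns else ""


@dataclass
class Saveframe:
    name: str
    tags: dict[str, str | None] = field(default_factory=dict)
    loops: list[Loop] = field(default_factory=list)

    def loop(self, category: str) -> Loop | None:
        for lp in self.loops:
            if lp.category == category:
                return lp
        return None


@dataclass
class DataBlock:
    name: str
    frames: dict[str, Saveframe] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# tokenizer


def _tokenize(text: str):
    """Yield (kind, value) with kind in {token, value}; quoting resolved."""
    i, n = 0, len(text)
    at_line_start = True
    while i < n:
        c = text[i]
        if c in " \t":
            i += 1
            continue
        if c == "\n":
            i += 1
            at_line_start = True
            continue
        if c == "#":
            while i < n and text[i] != "\n":
                i += 1
            continue
        if c == ";" and at_line_start:
            # multi-line value: up to a line starting with ';'
            j = text.find("\n;", i + 1)
            if j < 0:
                raise ParseError("unterminated semicolon-delimited value")
            yield ("value", text[i + 1 : j].lstrip("\n"))
            i = j + 2
            continue
        at_line_start = False
        if c in "'\"":
            j = i + 1
            while j < n and text[j] != c:
                j += 1
            if j >= n:
                raise ParseError(f"unterminated quoted string near: {text[i:i+30]!r}")
            yield ("value", text[i + 1 : j])
            i = j + 1
            continue
        j = i
        while j < n and text[j] not in " \t\n#":
            j += 1
        yield ("token", text[i:j])
        i = j


def parse(text: str) -> DataBlock:
    """Parse one data block of STAR text."""
    tokens = list(_tokenize(text))
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else (None, None)

    block: DataBlock | None = None
    frame: Saveframe | None = None
    while pos < len(tokens):
        kind, tok = tokens[pos]
        if kind == "token" and tok.startswith("data_"):
            if block is not None:
                raise ParseError("multiple data blocks are not supported")
            block = DataBlock(name=tok[5:])
            pos += 1
            continue
        if block is None:
            raise ParseError(f"content before data_ block: {tok!r}")
        if kind == "token" and tok == "save_" and frame is not None:
            block.frames[frame.name] = frame
            frame = None
            pos += 1
            continue
        if kind == "token" and tok.startswith("save_"):
            if frame is not None:
                raise ParseError(f"nested saveframe {tok!r}")
            frame = Saveframe(name=tok[5:])
            pos += 1
            continue
        if frame is None:
            raise ParseError(f"content outside a saveframe: {tok!r}")
        if kind == "token" and tok == "loop_":
            pos += 1
            columns: list[str] = []
            while pos < len(tokens):
                k, t = tokens[pos]
                if k == "token" and t.startswith("_"):
                    columns.append(t)
                    pos += 1
                else:
                    break
            if not columns:
                raise ParseError("loop_ without column headers")
            values: list[str | None] = []
            while pos < len(tokens):
                k, t = tokens[pos]
                if k == "token" and t == "stop_":
                    pos += 1
                    break
                if k == "token" and (
                    t in ("loop_", "save_") or t.startswith("save_")
                ):
                    raise ParseError(
                        f"loop of category {columns[0]!r} not closed by stop_"
                    )
                values.append(None if (k == "token" and t == NULL) else t)
                pos += 1
            if len(values) % len(columns) != 0:
                raise ParseError(
                    f"loop {columns[0]!r}: {len(values)} values do not fill "
                    f"rows of {len(columns)} columns"
                )
            rows = [
                values[r : r + len(columns)]
                for r in range(0, len(values), len(columns))
            ]
            frame.loops.append(Loop(columns=columns, rows=rows))
            continue
        if kind == "token" and tok.startswith("_"):
            pos += 1
            k, v = peek()
            if k is None:
                raise ParseError(f"tag {tok!r} without a value")
            pos += 1
            frame.tags[tok] = None if (k == "token" and v == NULL) else v
            continue
        raise ParseError(f"unexpected token {tok!r}")
    if frame is not None:
        raise ParseError(f"saveframe {frame.name!r} not closed by save_")
    if block is None:
        raise ParseError("no data_ block found")
    return block


# ---------------------------------------------------------------------------
# writer


def _format_value(value: str | None) -> str:
    if value is None or value == "":
        return NULL
    needs_quote = (
        any(ch in value for ch in " \t'\"")
        or value.startswith(("_", "#", ";"))
        or value in (NULL, "?")
        or value.startswith(("data_", "save_", "loop_", "stop_"))
    )
    if "\n" in value:
        return "\n;\n" + value + "\n;\n"
    if needs_quote:
        if "'" not in value:
            return f"'{value}'"
        if '"' not in value:
            return f'"{value}"'
        return "\n;\n" + value + "\n;\n"
    return value


def serialize(block: DataBlock) -> str:
    out: list[str] = [f"data_{block.name}", ""]
    for frame in block.frames.values():
        out.append(f"save_{frame.name}")
        width = max((len(t) for t in frame.tags), default=0)
        for tag, value in frame.tags.items():
            out.append(f"   {tag:<{width}}   {_format_value(value)}")
        for lp in frame.loops:
            out.append("   loop_")
            for col in lp.columns:
                out.append(f"      {col}")
            for row in lp.rows:
                out.append(
                    "      " + "   ".join(_format_value(v) for v in row)
                )
            out.append("   stop_")
        out.append("save_")
        out.append("")
    return "\n".join(out) + "\n"
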