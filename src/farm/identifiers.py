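"""Reversible encoding of arbitrary identifiers into SBML SIds.

SBML identifiers must match ``[A-Za-z_][A-Za-z0-9_]*``, but metabolic
databases use ids like ``CPD[c]`` or ``1diacyl``.  Each disallowed
character is substituted by its ASCII code point demarcated by double
underscores (``[`` is ASCII 91, so it becomes ``__91__``), and a
digit-initial result is prefixed with a single underscore
(``1diacyl`` → ``_1diacyl``).

The naive substitution alone is not injective: a raw string that already
contains a token-shaped substring (``a__91__b``) or starts with an
underscore followed by a digit would decode to something else.  When
:func:`encode_identifier` detects that the naive encoding would not
round-trip, it falls back to also encoding every underscore (ASCII 95),
which removes the ambiguity.  ``decode_identifier(encode_identifier(x))
== x`` therefore holds for every printable-ASCII string.
"""

from __future__ import annotations

import re

_ALLOWED = re.compile(r"[A-Za-z0-9_]")
_SID = re.compile(r"[A-Za-z_][A-Za-z0-9_]*\Z")
_TOKEN = re.compile(r"__(\d+)__")


class CodecError(ValueError):
    pass


def is_valid_sid(s: str) -> bool:
    return bool(_SID.match(s))


def _substitute(raw: str, escape_underscore: bool) -> str:
    out = []
    for ch in raw:
        if ch == "_" and escape_underscore:
            out.append("__95__")
        elif _ALLOWED.match(ch):
            out.append(ch)
        else:
            out.append(f"__{ord(ch)}__")
    encoded = "".join(out)
    if encoded and encoded[0].isdigit():
        encoded = "_" + encoded
    return encoded


def encode_identifier(raw: str) -> str:
    """Encode ``raw`` into an SBML-safe identifier (losslessly)."""
    if not raw:
        raise CodecError("cannot encode an empty identifier")
    basic = _substitute(raw, escape_underscore=False)
    try:
        if decode_identifier(basic) == raw:
            return basic
    except CodecError:
        pass
    full = _substitute(raw, escape_underscore=True)
    if decode_identifier(full) != raw:  # pragma: no cover - defensive
        raise CodecError(f"identifier {raw!r} cannot be encoded reversibly")
    return full


def decode_identifier(sid: str) -> str:
    """Invert :func:`encode_identifier`.

    A numeric token whose code point falls outside the printable ASCII
    range is malformed and raises :class:`CodecError` naming the token.
    Already-legal identifiers pass through unchanged.
    """
    s = sid
    if len(s) > 1 and s[0] == "_" and s[1].isdigit():
        s = s[1:]

    def repl(match: re.Match) -> str:
        code = int(match.group(1))
        if not (32 <= code <= 126):
            raise CodecError(f"malformed identifier token {match.group(0)!r}: "
                             f"code point {code} is not printable ASCII")
        return chr(code)

    return _TOKEN.sub(repl, s)
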