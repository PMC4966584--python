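"""Shared tokenization used by both term mining and query matching.

Mining and matching must use the same token definition, otherwise mined
keywords could fail to match the very documents they were counted in.
Tokens are maximal alphanumeric runs, lower-cased.  Length and stop-word
filtering are applied only when selecting candidate keywords, never when
matching a query against a record.
"""

from __future__ import annotations

import re
from functools import lru_cache
from importlib import resources

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")

#: Minimum keyword length for mining (matching has no such limit).
MIN_KEYWORD_LEN = 3


def tokenize(text: str) -> list[str]:
    """Split free text into lower-cased alphanumeric tokens."""
    return [t.lower() for t in _TOKEN_RE.findall(text)]


@lru_cache(maxsize=1)
def stopwords() -> frozenset[str]:
    """The versioned stop-word list shipped with the package."""
    raw = resources.files("filterforge.data").joinpath("stopwords.txt").read_text()
    words = set()
    for line in raw.splitlines():
        line = line.strip().lower()
        if line and not line.startswith("#"):
            words.add(line)
    return frozenset(words)


def is_keyword(token: str) -> bool:
    """True if a token qualifies as a minable keyword."""
    return len(token) >= MIN_KEYWORD_LEN and token not in stopwords()
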