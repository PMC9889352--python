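"""Text normalization shared by the lexicon loader and the classifier."""

from __future__ import annotations

import re

_NON_WORD = re.compile(r"[^\w\s-]")
# a hyphen survives only between two word characters ("non-small")
_DANGLING_HYPHEN = re.compile(r"(?<!\w)-|-(?!\w)")
_WS = re.compile(r"\s+")


def normalize_text(text: str) -> str:
    """Canonicalize free text for matching.

    Lowercases, replaces punctuation with spaces (keeping intra-word
    hyphens), and collapses whitespace runs. Idempotent:
    ``normalize_text(normalize_text(x)) == normalize_text(x)``.
    """
    text = text.lower()
    text = _NON_WORD.sub(" ", text)
    text = _DANGLING_HYPHEN.sub(" ", text)
    return _WS.sub(" ", text).strip()
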