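"""Token-frequency summaries of enriched term names and descriptions.

Term strings are lowercased and split on runs of non-alphanumeric
characters (so hyphenated terms like "protein-containing" split into two
tokens); tokens shorter than 3 characters and tokens on the built-in
English stopword list are dropped.  The per-condition top-k token sets
(default k = 20) are compared with an exact three-way Venn partition.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

# Fixed, versioned stopword list shipped with the package so token counts
# are reproducible across installations.
STOPWORDS = frozenset("""
a about above after again against all also although among amongst an and any
are aren as at be because been before being below between both but by can
cannot could did do does doing down during each few for from further had has
have having he her here hers him his how however if in into is it its itself
just more most much must my no nor not now of off on once only onto or other
our ours out over own same she should so some such than that the their theirs
them then there these they this those through thus to too under until up upon
via was we were what when where which while who whom why will with within
without would you your yours
""".split())

# Minimal suffix stripper; off by default — enable only when merging plural
# and gerund variants is desired.
_STEM_SUFFIXES = ("ations", "ation", "ings", "ing", "ies", "es", "s")

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def _stem(token: str) -> str:
    for suf in _STEM_SUFFIXES:
        if token.endswith(suf) and len(token) - len(suf) >= 3:
            return token[: -len(suf)]
    return token


def tokenize_terms(term_strings, stem: bool = False) -> Counter:
    """Aggregate token counts over a list of term name/description strings."""
    counts: Counter = Counter()
    for s in term_strings:
        for token in _TOKEN_RE.findall(str(s).lower()):
            if len(token) < 3 or token in STOPWORDS:
                continue
            counts[_stem(token) if stem else token] += 1
    return counts


def top_tokens(counts: Counter, k: int = 20) -> list[str]:
    """The k highest-count tokens, ties broken by token ascending."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [t for t, _ in ranked[:k]]


def venn_partition(set_a, set_b) -> tuple[set, set, set]:
    """Exact three-way partition (only_a, shared, only_b) of two sets."""
    a, b = set(set_a), set(set_b)
    return a - b, a & b, b - a


@dataclass
class TokenSummary:
    """Token counts and top-k ranking for one condition's enriched terms."""

    condition: str
    counts: Counter
    top_k: list[str]

    @classmethod
    def from_terms(cls, condition: str, term_strings, k: int = 20,
                   stem: bool = False) -> "TokenSummary":
        counts = tokenize_terms(term_strings, stem=stem)
        return cls(condition, counts, top_tokens(counts, k) if counts else [])
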