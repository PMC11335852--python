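"""A fixed English stop-word list for the word-level (WL) bridge.

Function words carry little picturable content, so the word-level
variant drops them before regressing each remaining word onto its image
vector ("there is a dog on the floor" -> "dog floor"). The list is a
conventional ~120-entry closed-class inventory (articles, pronouns,
prepositions, auxiliaries, conjunctions); it is packaged verbatim so the
transformation is reproducible.
"""
from __future__ import annotations

STOP_WORDS: frozenset[str] = frozenset("""
a about above after again against all am an and any are as at be because
been before being below between both but by can could did do does doing
down during each few for from further had has have having he her here hers
herself him himself his how i if in into is it its itself just me more most
my myself no nor not now of off on once only or other our ours ourselves
out over own same she should so some such than that the their theirs them
themselves then there these they this those through to too under until up
very was we were what when where which while who whom why will with would
you your yours yourself yourselves
""".split())


def remove_stop_words(tokens: list[str]) -> list[str]:
    """Drop stop words, preserving the order of the remaining tokens."""
    return [t for t in tokens if t not in STOP_WORDS]
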