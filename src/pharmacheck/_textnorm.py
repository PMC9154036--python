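"""Case- and diacritic-insensitive text normalisation for drug labels and
French problem keywords ("Épilepsie" ≡ "epilepsie")."""

from __future__ import annotations

import unicodedata


def fold(text: str) -> str:
    """Lowercase and strip combining marks (NFKD decomposition)."""
    decomposed = unicodedata.normalize("NFKD", text.casefold())
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))
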