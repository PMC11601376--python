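"""Tiny DNA sequence helpers shared across modules."""

from __future__ import annotations

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]
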