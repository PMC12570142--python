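"""Deterministic fan-out of one global seed into per-component seeds.

Every pipeline stage (fixture generation, split, training, generation, ...)
gets its own seed derived from the global one with a stable label hash, so a
sub-step can be reproduced in isolation without replaying the whole run.
"""

from __future__ import annotations

import hashlib


def derive_seed(master: int, label: str) -> int:
    """A per-component seed in [0, 2^31) derived from (master, label) via
    SHA-256; stable across platforms and Python versions."""
    digest = hashlib.sha256(f"{master}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)
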