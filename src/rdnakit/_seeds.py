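"""Deterministic derivation of per-stage seeds from one global seed."""

import hashlib


def derive_seed(seed: int, stage: str) -> int:
    """Expand a global seed into a stage-specific seed below 2**31.

    Hash-based so that adding or re-ordering stages never shifts the seed of
    an unrelated stage, which keeps stage outputs re-runnable in isolation.
    """
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
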