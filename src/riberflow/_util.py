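"""Small shared helpers: seed streams, rounding, config hashing."""

from __future__ import annotations

import hashlib
import json

import numpy as np

# Every generator draws from its own named stream so that adding a stage
# never perturbs the randomness of another.  Streams are derived from the
# single user seed via SeedSequence spawn keys.
_STREAMS = {
    "rip": 1,
    "gene_models": 2,
    "nascent": 3,
    "intervals": 4,
    "lfq": 5,
    "overlap_test": 6,
    "segment_enrichment": 7,
    "permutation_fdr": 8,
}


def rng_for(seed: int, stream: str) -> np.random.Generator:
    """Generator for a named randomness stream derived from ``seed``."""
    key = _STREAMS[stream]
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero (45.5 -> 46)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def percent(k: float, n: float) -> int:
    """Integer percentage k/n with half-up rounding, as printed in reports."""
    if n == 0:
        raise ZeroDivisionError("percent of an empty denominator")
    return round_half_up(100.0 * k / n)


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def dump_json(obj, path) -> None:
    """Deterministic JSON writer (sorted keys, fixed separators)."""
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=2)
        fh.write("\n")
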