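"""Small shared helpers: pair keys, errors, logging."""

from __future__ import annotations

import hashlib
import json
import logging

logger = logging.getLogger("plnet")


class PlnetError(Exception):
    """Base class for errors raised by plnet."""


class FormatError(PlnetError):
    """A file did not conform to the documented format."""


class CyclicOntologyError(PlnetError):
    """The parsed ontology graph contains a cycle."""


class UnknownParentError(PlnetError):
    """A term references a parent that is not defined in the file."""


class InsufficientBenchmarkOverlap(PlnetError):
    """Too few benchmarked pairs to form at least two full bins."""


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered key for a gene pair.

    Raises ValueError for self-pairs: the networks built here are simple
    graphs and a gene cannot be functionally linked to itself.
    """
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


def config_hash(params: dict) -> str:
    """Stable short hash of a parameter dict, for output-file audit headers."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
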