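"""Run configuration shared by the lexicon builder, matcher and CLI."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

#: Small fixed English stop-word list; enough to reduce phrases like
#: "aplasia of the hallux" to their content words. Configurable off.
DEFAULT_STOP_WORDS = frozenset(
    "a an and in of on or the to with".split()
)

#: Name-type weights by scope. LABEL and EXACT synonyms carry full weight;
#: looser synonym scopes are discounted.
DEFAULT_WEIGHTS = {
    "LABEL": 1.0,
    "EXACT": 1.0,
    "NARROW": 0.9,
    "BROAD": 0.9,
    "RELATED": 0.8,
}

#: Crop/plant ontologies rely mainly on narrow synonyms, so the plant profile
#: raises their weight to full.
PLANT_WEIGHTS = {**DEFAULT_WEIGHTS, "NARROW": 1.0}

WEIGHT_PROFILES = {"default": DEFAULT_WEIGHTS, "plant": PLANT_WEIGHTS}


@dataclass(frozen=True)
class MatchConfig:
    """Parameters of the compound-matching pipeline.

    t1, t2
        The two similarity thresholds: ``t1`` filters the first-pass
        (recall-oriented) source/target-1 mappings, ``t2`` filters the final
        compound mappings on the average of the two step similarities.
        Defaults 0.4 and 0.9.
    weights
        Multiplicative name-type weights by scope (LABEL/EXACT/NARROW/...).
    stemming
        Apply the Porter stemmer to tokens (on by default; turning it off
        makes tokenization a pure lowercase/split/stop-word filter).
    """

    t1: float = 0.4
    t2: float = 0.9
    weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    stemming: bool = True
    stop_words: frozenset = DEFAULT_STOP_WORDS
    selector: str | None = None  # None, "top1" or "top2"
    tie_break: str = "lex"  # "lex" or "random"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.t1 <= 1.0) or not (0.0 < self.t2 <= 1.0):
            raise ValueError("thresholds must lie in (0, 1]")
        if self.selector not in (None, "top1", "top2"):
            raise ValueError(f"unknown selector {self.selector!r}")
        if self.tie_break not in ("lex", "random"):
            raise ValueError(f"unknown tie-break mode {self.tie_break!r}")

    def weight(self, scope: str) -> float:
        return self.weights.get(scope, self.weights.get("RELATED", 0.8))

    def with_profile(self, profile: str) -> "MatchConfig":
        if profile not in WEIGHT_PROFILES:
            raise ValueError(f"unknown weights profile {profile!r}")
        return replace(self, weights=dict(WEIGHT_PROFILES[profile]))

    def to_dict(self) -> dict:
        d = {
            "t1": self.t1,
            "t2": self.t2,
            "weights": dict(self.weights),
            "stemming": self.stemming,
            "stop_words": sorted(self.stop_words),
            "selector": self.selector,
            "tie_break": self.tie_break,
            "seed": self.seed,
        }
        return d

    def digest(self) -> str:
        """Short stable hash of the configuration, recorded in alignment provenance."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "MatchConfig":
        """Load a YAML config file; keyword overrides win over file values."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        profile = data.pop("weights_profile", None)
        if "stop_words" in data:
            data["stop_words"] = frozenset(data["stop_words"])
        data.update(overrides)
        cfg = cls(**data)
        if profile and "weights" not in data:
            cfg = cfg.with_profile(profile)
        return cfg
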