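"""Run configuration: one plain-text file mirroring every CLI flag.

The file uses ini-style ``key = value`` sections; unknown keys are rejected
so typos fail loudly.  The CLI parses the config first and lets explicit
flags override it; both are logged at run start.
"""

from __future__ import annotations

import configparser
import hashlib
import io
import json
from dataclasses import asdict, dataclass, fields


@dataclass
class RunConfig:
    # corpus
    lenk: int = 5
    flank: int = 50
    top_n: int = 1500
    seq_len: int = 101
    n_pos: int = 150
    # model
    dc: int = 50
    ds: int = 50
    dj: int = 50
    dsq: int = 150
    epochs: int = 30
    lr0: float = 0.001
    decay: float = 0.001
    loss: str = "iterloss"
    # motif assembly
    min_sites: int = 5
    pseudocount: float = 0.25
    max_mismatch_frac: float = 0.25
    mi_metric: str = "dot"
    threshold: float = 0.5
    seed: int = 0

    _SECTIONS = {
        "corpus": ("lenk", "flank", "top_n", "seq_len", "n_pos"),
        "model": ("dc", "ds", "dj", "dsq", "epochs", "lr0", "decay", "loss"),
        "motifs": ("min_sites", "pseudocount", "max_mismatch_frac",
                   "mi_metric", "threshold", "seed"),
    }

    def validate(self, motif_discovery: bool = True) -> None:
        if not 3 <= self.lenk <= 8:
            raise ValueError("lenk must lie in [3, 8]")
        if motif_discovery and self.dsq != self.dc + self.ds + self.dj:
            raise ValueError(
                "motif discovery requires dsq = dc + ds + dj "
                f"(got {self.dsq} vs {self.dc + self.ds + self.dj})"
            )

    def serialize(self) -> str:
        cp = configparser.ConfigParser()
        for section, keys in self._SECTIONS.items():
            cp[section] = {k: repr(getattr(self, k)) for k in keys}
        buf = io.StringIO()
        cp.write(buf)
        return buf.getvalue()

    @classmethod
    def parse(cls, text: str) -> "RunConfig":
        cp = configparser.ConfigParser()
        cp.read_string(text)
        known = {f.name: f.type for f in fields(cls)}
        types = {f.name: type(getattr(cls(), f.name)) for f in fields(cls)}
        kwargs = {}
        for section in cp.sections():
            for key, raw in cp[section].items():
                if key not in known:
                    raise ValueError(f"unknown configuration key {key!r}")
                t = types[key]
                val = raw.strip().strip("'\"")
                kwargs[key] = t(val) if t is not str else val
        return cls(**kwargs)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.parse(fh.read())

    def save(self, path) -> None:
        from .io import atomic_write

        with atomic_write(path) as fh:
            fh.write(self.serialize())

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]
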