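"""Run configuration: the plain-text key/value parameter file.

The configuration dialect is one ``key <separator> value`` pair per
line, '#' comments, keys matched case-insensitively after whitespace
normalization.  Both the long human-readable parameter names used in the
original input-file convention (e.g. ``Max degeneracy (base pairs)``)
and snake_case field names (``max_degeneracy``) are accepted.  The
separator may be a tab, an '=', or simply the last whitespace run before
the value (the long names are matched as prefixes).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, fields, replace
from pathlib import Path


@dataclass
class ConfigParams:
    """All tunable knobs of the pipeline.

    Melting temperatures are in degrees centigrade, lengths in base
    pairs.  ``heating`` is the dimensionless H in the Metropolis uphill
    acceptance probability exp(-deltaS * H).
    """

    background_path: str | None = None
    consensus_path: str | None = None
    exceptions_path: str | None = None
    max_degeneracy: int = 3
    tm_min: int = 50
    tm_max: int = 60
    amplicon_min: int = 50
    amplicon_max: int = 250
    initial_overlap: int = 0
    n_iterations: int = 10000
    max_gap: int = 10
    save_interim: bool = False
    verbose: bool = False
    cost_tolerance: int = 0
    output_path: str = "primer_design_results.out"
    restart: bool = False
    prob_remove_redundant: float = 0.0
    early_proportion: float = 0.0
    weight_greedy: bool = True
    remove_nonreusable: bool = False
    heating: float = 0.2
    primer_len_min: int = 18
    primer_len_max: int = 27
    max_redundancy: int = 10
    rng_seed: int = 0
    #: "boltzmann" accepts uphill moves with exp(-deltaS*H); "fraction"
    #: accepts a fixed fraction H of uphill proposals.
    acceptance_mode: str = "boltzmann"

    def validate(self) -> None:
        errors = []
        if self.tm_min > self.tm_max:
            errors.append("tm_min > tm_max")
        if self.primer_len_min > self.primer_len_max:
            errors.append("primer_len_min > primer_len_max")
        if not (2 * self.primer_len_min <= self.amplicon_min <= self.amplicon_max):
            errors.append(
                "need 2*primer_len_min <= amplicon_min <= amplicon_max"
            )
        for name in ("prob_remove_redundant", "early_proportion"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                errors.append(f"{name} not in [0, 1]")
        if self.heating < 0:
            errors.append("heating < 0")
        if self.n_iterations < 1:
            errors.append("n_iterations < 1")
        if self.max_degeneracy < 0:
            errors.append("max_degeneracy < 0")
        if self.max_redundancy < 1:
            errors.append("max_redundancy < 1")
        if self.acceptance_mode not in ("boltzmann", "fraction"):
            errors.append("acceptance_mode must be 'boltzmann' or 'fraction'")
        if errors:
            raise ConfigError("invalid configuration: " + "; ".join(errors))

    def with_(self, **kwargs) -> "ConfigParams":
        cfg = replace(self, **kwargs)
        cfg.validate()
        return cfg


class ConfigError(ValueError):
    pass


def _norm(s: str) -> str:
    s = s.lower()
    s = re.sub(r"[^a-z0-9() _]", " ", s)
    s = re.sub(r"\s+", " ", s).strip()
    return s


#: normalized long-form key -> field name (includes the original
#: convention's spelling quirks)
_ALIASES: dict[str, str] = {
    "genome file for blast searching": "background_path",
    "sequences to amplify file": "consensus_path",
    "exceptions file": "exceptions_path",
    "max degeneracy (base pairs)": "max_degeneracy",
    "minumum melting temperature (centigrade)": "tm_min",
    "minimum melting temperature (centigrade)": "tm_min",
    "maximum melting temperature (centigrade)": "tm_max",
    "minimum amplicon length (base pairs)": "amplicon_min",
    "maximum amplicon length (base pairs)": "amplicon_max",
    "initial overlap (base pairs)": "initial_overlap",
    "number of optimisations": "n_iterations",
    "number of optimizations": "n_iterations",
    "maximum gap between sequences (base pairs)": "max_gap",
    "save interim optimizations": "save_interim",
    "verbose output": "verbose",
    "cost tolerance": "cost_tolerance",
    "output file name": "output_path",
    "restart from previous run": "restart",
    "probability of removing redundant primer pairs": "prob_remove_redundant",
    "proportion of iterations to be considered as early": "early_proportion",
    "weight greedy methods according to optimization": "weight_greedy",
    "remove non reusable primers from initial design": "remove_nonreusable",
    "proportion of failed weight check proposals to accept (heating)": "heating",
    "minimum primer length (base pairs)": "primer_len_min",
    "maximum primer length (base pairs)": "primer_len_max",
    "maximum redundancy": "max_redundancy",
    "rng seed": "rng_seed",
    "acceptance mode": "acceptance_mode",
}
# snake_case canonical names are always accepted
for _f in fields(ConfigParams):
    _ALIASES[_norm(_f.name)] = _f.name

_FIELD_TYPES = {f.name: f.type for f in fields(ConfigParams)}

_STR_FIELDS = {
    "background_path", "consensus_path", "exceptions_path",
    "output_path", "acceptance_mode",
}
_BOOL_FIELDS = {
    "save_interim", "verbose", "restart", "weight_greedy", "remove_nonreusable",
}
_FLOAT_FIELDS = {"prob_remove_redundant", "early_proportion", "heating"}


def _coerce(field_name: str, raw: str):
    raw = raw.strip()
    if field_name in _STR_FIELDS:
        return raw
    if field_name in _BOOL_FIELDS:
        if raw in ("0", "1"):
            return raw == "1"
        low = raw.lower()
        if low in ("true", "yes", "on"):
            return True
        if low in ("false", "no", "off"):
            return False
        raise ConfigError(f"flag {field_name!r} must be 0 or 1, got {raw!r}")
    if field_name in _FLOAT_FIELDS:
        return float(raw)
    return int(raw)


def _split_line(line: str) -> tuple[str, str]:
    """Split a config line into (key, value)."""
    if "\t" in line:
        key, _, value = line.partition("\t")
        return key, value
    if "=" in line:
        key, _, value = line.partition("=")
        return key, value
    # space-separated: take the longest leading chunk that normalizes to a
    # known key; the untouched remainder is the value
    splits = [m.start() for m in re.finditer(r"\s+", line)]
    for pos in reversed(splits):
        if _norm(line[:pos]) in _ALIASES:
            return line[:pos], line[pos:]
    raise ConfigError(f"cannot parse configuration line: {line!r}")


def parse_config(path: str | Path) -> ConfigParams:
    """Parse a plain-text configuration file into ConfigParams.

    Missing keys take their defaults; unknown keys are rejected;
    invariant violations raise :class:`ConfigError` naming the fields.
    """
    values: dict[str, object] = {}
    with open(path) as fh:
        for lineno, raw_line in enumerate(fh, start=1):
            line = raw_line.split("#", 1)[0].strip()
            if not line:
                continue
            key, value = _split_line(line)
            field_name = _ALIASES.get(_norm(key))
            if field_name is None:
                raise ConfigError(
                    f"{path}:{lineno}: unknown configuration key {key.strip()!r}"
                )
            try:
                values[field_name] = _coerce(field_name, value)
            except (ValueError, ConfigError) as exc:
                raise ConfigError(f"{path}:{lineno}: {exc}") from None
    cfg = ConfigParams(**values)
    cfg.validate()
    return cfg


def write_config(cfg: ConfigParams, path: str | Path) -> None:
    """Write a ConfigParams as a snake_case key=value file."""
    with open(path, "w") as fh:
        for f in fields(ConfigParams):
            v = getattr(cfg, f.name)
            if v is None:
                continue
            if isinstance(v, bool):
                v = int(v)
            fh.write(f"{f.name} = {v}\n")
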