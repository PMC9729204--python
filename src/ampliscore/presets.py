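"""Task presets and run configuration.

A preset fixes the three parameters that distinguish the PCR variants: the
primer orientation, the primer-to-primer distance range (product size for
face-to-face designs) and the distance from the first primer to the target
spot.  Ranges are written as four comma-separated numbers -- the minimum
and maximum of the optimal range, then the minimum and maximum of the
permitted range -- and are extended to the six-parameter piecewise logistic
form by adding the same saturation margins the built-in defaults use
(20 bases beyond the permitted distance range, 0 beyond the permitted
position range).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .design import DesignTask
from .score_model import ModelParams
from .thermo import ThermoConditions


class PresetError(ValueError):
    """Unknown preset or malformed configuration."""


def range4_to_params(values, lo_margin: float, hi_margin: float
                     ) -> ModelParams:
    """(opt_min, opt_max, perm_min, perm_max) + saturation margins ->
    six-parameter model."""
    if isinstance(values, str):
        values = [float(v) for v in values.split(",")]
    values = [float(v) for v in values]
    if len(values) == 6:
        return ModelParams(*values)
    if len(values) != 4:
        raise PresetError(f"expected 4 (or 6) numbers, got {values}")
    opt_min, opt_max, perm_min, perm_max = values
    return ModelParams(opt_min, opt_max, perm_min, perm_max,
                       perm_min - lo_margin, perm_max + hi_margin)


_DIS_MARGIN = 20.0  # built-in f(Dis) default: Min-MinL = MaxL-Max = 20
_POS_MARGIN = 0.0   # built-in f(Pos) default: limits equal the permitted range

# preset name -> (task, orientation, dis range4, pos range4 or None)
_PRESETS: dict[str, tuple[str, str, tuple, tuple | None]] = {
    "generic": ("generic", "face-to-face", (120, 160, 80, 200), None),
    "sanger_genotyping": ("genotyping", "face-to-face",
                          (530, 570, 500, 600), (100, 150, 70, 300)),
    "arms": ("arms", "face-to-face", (120, 160, 80, 200), (0, 0, 0, 0)),
    "inverse": ("inverse", "back-to-back", (5, 10, 0, 15), (10, 20, 5, 45)),
    "anchored": ("anchored", "unidirectional", (-15, -10, -30, -5),
                 (10, 20, 5, 45)),
    "full_covered": ("full_covered", "face-to-face",
                     (120, 160, 80, 200), None),
}


@dataclass(frozen=True)
class RunConfig:
    """Everything a design run needs, after preset expansion."""

    task: DesignTask
    conditions: ThermoConditions = ThermoConditions()
    word_size: int = 7
    dimer_threshold_tm: float = 45.0
    model_overrides: Mapping[str, ModelParams] = field(default_factory=dict)
    seed: int = 0


def apply_preset(preset: str, **overrides) -> RunConfig:
    """Expand a named preset into a RunConfig; keyword overrides win.

    Overrides accept DesignTask field names (``opt_tm``, ``n_return``,
    ``min_len``...), ``dis`` / ``pos`` as four- or six-number ranges, and
    RunConfig field names (``word_size``, ``conditions``...).
    """
    if preset not in _PRESETS:
        raise PresetError(
            f"unknown preset {preset!r}; valid: {sorted(_PRESETS)}")
    task_name, orientation, dis4, pos4 = _PRESETS[preset]
    dis = range4_to_params(overrides.pop("dis", dis4),
                           _DIS_MARGIN, _DIS_MARGIN)
    pos_src = overrides.pop("pos", pos4)
    pos = (range4_to_params(pos_src, _POS_MARGIN, _POS_MARGIN)
           if pos_src is not None else DesignTask.__dataclass_fields__[
               "pos_params"].default)
    task_fields = {f.name for f in dataclasses.fields(DesignTask)}
    task_kw = {k: overrides.pop(k) for k in list(overrides)
               if k in task_fields}
    task = DesignTask(task=task_name, orientation=orientation,
                      dis_params=dis, pos_params=pos, **task_kw)
    cfg_fields = {f.name for f in dataclasses.fields(RunConfig)}
    cfg_kw = {k: overrides.pop(k) for k in list(overrides)
              if k in cfg_fields}
    if overrides:
        raise PresetError(f"unknown configuration keys {sorted(overrides)}")
    return RunConfig(task=task, **cfg_kw)


def load_config(path: str | Path) -> dict[str, object]:
    """Flat key=value configuration file.

    ``model.<Feature> = six,comma,numbers`` overrides a feature model;
    ``dis``/``pos`` take four or six numbers; everything else is parsed as
    int/float/string.  Returns a keyword dict for :func:`apply_preset`.
    """
    out: dict[str, object] = {}
    model_overrides: dict[str, ModelParams] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise PresetError(f"{path} line {lineno}: expected key = value")
        key, value = (s.strip() for s in line.split("=", 1))
        if key.startswith("model."):
            model_overrides[key[6:]] = ModelParams.from_sequence(value)
        elif key in ("dis", "pos"):
            out[key] = [float(v) for v in value.split(",")]
        else:
            out[key] = _parse_scalar(value)
    if model_overrides:
        out["model_overrides"] = model_overrides
    return out


def _parse_scalar(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    return value


def config_echo(cfg: RunConfig) -> list[str]:
    """The effective configuration as key=value lines, for result headers."""
    t = cfg.task
    lines = [
        f"task = {t.task}",
        f"orientation = {t.orientation}",
        "dis = " + ",".join(str(v) for v in t.dis_params.as_tuple()),
        "pos = " + ",".join(str(v) for v in t.pos_params.as_tuple()),
        f"opt_tm = {t.opt_tm}", f"n_return = {t.n_return}",
        f"min_len = {t.min_len}", f"max_len = {t.max_len}",
        f"pos_step = {t.pos_step}", f"len_step = {t.len_step}",
        f"efficiency_cutoff = {t.efficiency_cutoff}",
        f"max_pcr_size = {t.max_pcr_size}",
        f"word_size = {cfg.word_size}",
        f"dimer_threshold_tm = {cfg.dimer_threshold_tm}",
        f"oligo_conc = {cfg.conditions.oligo_conc}",
        f"monovalent = {cfg.conditions.monovalent}",
        f"divalent = {cfg.conditions.divalent}",
        f"dntp = {cfg.conditions.dntp}",
    ]
    for name, params in cfg.model_overrides.items():
        lines.append(f"model.{name} = "
                     + ",".join(str(v) for v in params.as_tuple()))
    return lines
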