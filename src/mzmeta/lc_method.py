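"""Parsing of EASY-nLC-style liquid-chromatography method text.

Nano-flow LC instruments store their method — most importantly the gradient
program — as free text inside the acquisition metadata rather than as
structured parameters.  This module parses a documented line-oriented
dialect into a :class:`GradientProgram` and attaches it to the instrument's
parameter tree so gradient settings take part in grouping and reporting.

The dialect (also emitted by :mod:`mzmeta.synthetic`)::

    Sample pickup: 2.0 µl
    Equilibration: 4.0 µl
    Gradient:
    0.0 / 5.0 / 300.0 / 5.0
    5.0 / 55.0 / 300.0 / 38.0
    60.0 / 5.0 / 300.0 / 95.0

Gradient rows are ``time_min / duration_min / flow_nl_min / percent_B``;
the table ends at the first blank or slash-free line.  Lines the parser does
not recognize are preserved verbatim — a gradient line is never silently
dropped, and a row that fails to parse raises an error naming its line
number.  Decimal commas are rejected outright: a silent 10× misreading of a
flow rate is worse than a refusal.

Real vendor method strings are not publicly documented; alternative dialects
can be registered per instrument model in :data:`PARSER_REGISTRY`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Tuple

from .model import InstrumentMetadata, MetadataError, ModuleType, SourceFloat

__all__ = [
    "GradientProgram",
    "GradientStep",
    "LCMethodError",
    "PARSER_REGISTRY",
    "attach_gradient",
    "parse_lc_method",
    "render_lc_method",
]

logger = logging.getLogger(__name__)


class LCMethodError(MetadataError):
    """LC method text could not be parsed; carries a 1-based line number."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class GradientStep:
    """One row of the gradient table.

    ``time_min`` is the step start (minutes from injection), ``duration_min``
    the step length, ``flow_nl_min`` the flow in nl/min and ``percent_b`` the
    mobile-phase B fraction in percent.
    """

    time_min: SourceFloat
    duration_min: SourceFloat
    flow_nl_min: SourceFloat
    percent_b: SourceFloat

    def __post_init__(self) -> None:
        if self.time_min < 0 or self.duration_min < 0:
            raise LCMethodError("step time and duration must be >= 0")
        if self.flow_nl_min <= 0:
            raise LCMethodError("flow must be > 0")
        if not 0 <= self.percent_b <= 100:
            raise LCMethodError("%B must lie in [0, 100]")


@dataclass
class GradientProgram:
    """A parsed LC method: ordered gradient steps plus volume settings."""

    steps: List[GradientStep] = field(default_factory=list)
    sample_volume_ul: Optional[SourceFloat] = None
    column_equilibration_ul: Optional[SourceFloat] = None
    unparsed: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        times = [float(step.time_min) for step in self.steps]
        if times and times[0] != 0.0:
            raise LCMethodError("gradient must start at time 0")
        for prev, cur in zip(times, times[1:]):
            if cur <= prev:
                raise LCMethodError(
                    "gradient step times must be strictly increasing")


_NUMBER = re.compile(r"^[0-9]+(?:\.[0-9]+)?$")
_ROW_SPLIT = re.compile(r"\s*/\s*")
_VOLUME_LINE = re.compile(
    r"^(Sample pickup|Equilibration):\s*(\S+)\s*(?:µl|µL|ul|uL)\s*$")


def _parse_number(token: str, line_number: int) -> SourceFloat:
    if "," in token:
        raise LCMethodError(
            f"decimal comma in {token!r}; this dialect accepts the decimal "
            "point only", line_number)
    if not _NUMBER.match(token):
        raise LCMethodError(f"not a number: {token!r}", line_number)
    return SourceFloat(token)


def parse_easy_nlc(method_text: str) -> GradientProgram:
    """Parse the documented EASY-nLC-style dialect (see module docstring)."""
    if not method_text:
        raise LCMethodError("empty method text")
    steps: List[GradientStep] = []
    unparsed: List[str] = []
    sample_volume = None
    equilibration = None
    in_table = False
    for number, raw in enumerate(method_text.splitlines(), start=1):
        line = raw.strip()
        if in_table:
            if line and "/" in line:
                tokens = _ROW_SPLIT.split(line)
                if len(tokens) != 4:
                    raise LCMethodError(
                        f"gradient row needs 4 fields "
                        f"(time / duration / flow / %B), got {len(tokens)}",
                        number)
                t, d, f, b = (_parse_number(tok, number) for tok in tokens)
                steps.append(GradientStep(t, d, f, b))
                continue
            in_table = False  # table ends at first blank / slash-free line
        if not line:
            continue
        if line == "Gradient:":
            in_table = True
            continue
        volume = _VOLUME_LINE.match(line)
        if volume:
            value = _parse_number(volume.group(2), number)
            if volume.group(1) == "Sample pickup":
                sample_volume = value
            else:
                equilibration = value
            continue
        unparsed.append(raw)
    return GradientProgram(
        steps=steps,
        sample_volume_ul=sample_volume,
        column_equilibration_ul=equilibration,
        unparsed=tuple(unparsed),
    )


#: Pluggable dialect registry keyed by instrument model; ``None`` is the
#: fallback used when no model-specific parser is registered (config key
#: ``lc_dialect`` selects an entry explicitly).
PARSER_REGISTRY: Dict[Optional[str], Callable[[str], GradientProgram]] = {
    None: parse_easy_nlc,
    "Thermo EASY-nLC": parse_easy_nlc,
}


def parse_lc_method(method_text: str, model: Optional[str] = None,
                    dialect: Optional[str] = None) -> GradientProgram:
    """Parse LC method text using the registered dialect for *model*.

    *dialect* forces a registry entry regardless of model.  Raises
    :class:`LCMethodError` with a line number on malformed gradient rows and
    on non-monotone step times.
    """
    key = dialect if dialect is not None else model
    parser = PARSER_REGISTRY.get(key, PARSER_REGISTRY[None])
    return parser(method_text)


def render_lc_method(program: GradientProgram) -> str:
    """Serialize a gradient program back into the dialect.

    ``parse(render(parse(text)))`` equals ``parse(text)``.
    """
    lines: List[str] = []
    if program.sample_volume_ul is not None:
        lines.append(f"Sample pickup: {program.sample_volume_ul.text} µl")
    if program.column_equilibration_ul is not None:
        lines.append(f"Equilibration: {program.column_equilibration_ul.text} µl")
    if program.steps:
        lines.append("Gradient:")
        for step in program.steps:
            lines.append(
                f"{step.time_min.text} / {step.duration_min.text} / "
                f"{step.flow_nl_min.text} / {step.percent_b.text}")
    lines.extend(program.unparsed)
    return "\n".join(lines)


def gradient_subtree(program: GradientProgram) -> dict:
    """Parameter subtree for a gradient: one child per step under
    zero-padded index keys."""
    width = max(2, len(str(max(len(program.steps) - 1, 0))))
    return {
        format(i, f"0{width}d"): {
            "Time [min]": step.time_min,
            "Duration [min]": step.duration_min,
            "Flow [nl/min]": step.flow_nl_min,
            "%B": step.percent_b,
        }
        for i, step in enumerate(program.steps)
    }


def attach_gradient(instrument: InstrumentMetadata) -> InstrumentMetadata:
    """Return a copy of an LC instrument with its parsed method merged into
    the parameter tree.

    Adds a ``"Gradient"`` subtree (zero-padded step indices), ``"Sample
    pickup [µl]"`` / ``"Equilibration [µl]"`` leaves where stated, and an
    ``"Unparsed method lines"`` subtree preserving unrecognized lines
    verbatim.  A parse failure logs a warning and returns the instrument
    unchanged — one bad method must not abort grouping a whole collection.
    Instruments without method text (or non-LC modules) are returned as-is.
    """
    if instrument.module_type is not ModuleType.LC or not instrument.method_text:
        return instrument
    try:
        program = parse_lc_method(instrument.method_text, instrument.model)
    except LCMethodError as exc:
        logger.warning("could not parse LC method of %r: %s",
                       instrument.model, exc)
        return instrument
    parameters = dict(instrument.parameters)
    if program.steps:
        parameters["Gradient"] = gradient_subtree(program)
    if program.sample_volume_ul is not None:
        parameters["Sample pickup [µl]"] = program.sample_volume_ul
    if program.column_equilibration_ul is not None:
        parameters["Equilibration [µl]"] = program.column_equilibration_ul
    if program.unparsed:
        width = max(2, len(str(len(program.unparsed) - 1)))
        parameters["Unparsed method lines"] = {
            format(i, f"0{width}d"): line
            for i, line in enumerate(program.unparsed)
        }
    return replace(instrument, parameters=parameters)
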