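"""Stereological read-outs from accumulated counts.

Per subject, counts are pooled across fields and the read-outs are
computed as ratios of sums (never as means of per-field ratios, which
would weight sparse fields equally with dense ones):

- septal volume density        VVsep = sum(Psep) / sum(Pref)
- mean linear intercept        Lm    = 2 d (sum(Pref) - sum(Psep)) / sum(I)
- mean transsectional wall     Lmw   = 2 d sum(Psep) / sum(I)
- airspace surface density     SVair = 2 sum(I) / (d sum(Pref))

with d the unit test-line length per grid point (104 um for the default
test system). Lm is the average airspace chord length along the test
lines and grows with alveolar enlargement; Lmw is its wall analog; SVair
is the standard intersection-density surface estimator with total test
length L = d * sum(Pref). Multiplying by a known lung volume converts
the densities to absolute septal volume and airspace surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .counting import DEFAULT_D_UM, FieldCounts
from .errors import UndefinedReadoutError


def _sums(counts: Iterable[FieldCounts]) -> tuple[int, int, int, int]:
    sp_non = sp_ref = sp_sep = s_i = 0
    for c in counts:
        sp_non += c.p_nonpar
        sp_ref += c.p_ref
        sp_sep += c.p_sep
        s_i += c.i_total
    return sp_non, sp_ref, sp_sep, s_i


def vv_sep(counts: Sequence[FieldCounts]) -> float:
    """Septal volume density: sum(Psep) / sum(Pref), in [0, 1]."""
    _, s_ref, s_sep, _ = _sums(counts)
    if s_ref == 0:
        raise UndefinedReadoutError(
            "VVsep undefined: no reference points (all fields fully "
            "non-parenchymal)"
        )
    return s_sep / s_ref

def lm(counts: Sequence[FieldCounts], d: float = DEFAULT_D_UM) -> float:
    """Mean linear intercept of the airspaces, in um.

    Lm = 2 d (sum(Pref) - sum(Psep)) / sum(I). With no intersections and
    no airspace points the field is solid tissue and Lm is 0 by
    convention; no intersections while airspace points exist leaves the
    estimator undefined.
    """
    if d <= 0:
        raise ValueError("d must be positive")
    _, s_ref, s_sep, s_i = _sums(counts)
    p_air = s_ref - s_sep
    if s_i == 0:
        if p_air == 0:
            return 0.0
        raise UndefinedReadoutError(
            f"Lm undefined: {p_air} airspace points but no intersections"
        )
    return 2.0 * d * p_air / s_i


def lmw(counts: Sequence[FieldCounts], d: float = DEFAULT_D_UM) -> float:
    """Mean transsectional wall length, in um: 2 d sum(Psep) / sum(I).

    The wall analog of Lm; by construction lm + lmw = 2 d sum(Pref)/sum(I).
    """
    if d <= 0:
        raise ValueError("d must be positive")
    _, _, s_sep, s_i = _sums(counts)
    if s_i == 0:
        if s_sep == 0:
            return 0.0
        raise UndefinedReadoutError(
            f"Lmw undefined: {s_sep} septal points but no intersections"
        )
    return 2.0 * d * s_sep / s_i


def sv_air(counts: Sequence[FieldCounts], d: float = DEFAULT_D_UM) -> float:
    """Airspace surface density, in 1/um: 2 sum(I) / (d sum(Pref))."""
    if d <= 0:
        raise ValueError("d must be positive")
    _, s_ref, _, s_i = _sums(counts)
    if s_ref == 0:
        raise UndefinedReadoutError("SVair undefined: no reference points")
    return 2.0 * s_i / (d * s_ref)


@dataclass
class SubjectSummary:
    """Pooled counts and read-outs for one subject (animal/lung)."""

    subject_id: str
    n_fields: int
    sum_p_nonpar: int
    sum_p_ref: int
    sum_p_sep: int
    sum_i: int
    vv_sep: float
    lm: float
    lmw: float
    sv_air: float
    v_sep_um3: float | None = None  # absolute septal volume
    s_air_um2: float | None = None  # absolute airspace surface


def summarize(
    counts: Sequence[FieldCounts],
    subject_id: str = "",
    d: float = DEFAULT_D_UM,
    lung_volume_um3: float | None = None,
) -> SubjectSummary:
    """Pool fields of one subject and compute all read-outs."""
    s_non, s_ref, s_sep, s_i = _sums(counts)
    summary = SubjectSummary(
        subject_id=subject_id,
        n_fields=len(counts),
        sum_p_nonpar=s_non,
        sum_p_ref=s_ref,
        sum_p_sep=s_sep,
        sum_i=s_i,
        vv_sep=vv_sep(counts),
        lm=lm(counts, d),
        lmw=lmw(counts, d),
        sv_air=sv_air(counts, d),
    )
    if lung_volume_um3 is not None:
        v, s = absolute_quantities(summary, lung_volume_um3)
        summary.v_sep_um3 = v
        summary.s_air_um2 = s
    return summary


def absolute_quantities(
    summary: SubjectSummary, lung_volume_um3: float
) -> tuple[float, float]:
    """Convert densities to absolute quantities given a lung volume.

    Returns (V_sep in um^3, S_air in um^2).
    """
    if lung_volume_um3 <= 0:
        raise ValueError("lung volume must be positive")
    return summary.vv_sep * lung_volume_um3, summary.sv_air * lung_volume_um3
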