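"""Library-free MS1/MS2 quantification of histone peptide forms.

The measurement model: every target form produces an MS1 isotope cluster
whose extracted ion chromatograms (XICs) are integrated between detected
peak boundaries, and identities are assigned by retention time.  Positional
isomers share one MS1 peak; their individual contributions are recovered
from MS2 by linear equations on the peak heights of fragment ions whose
cleavage site falls between two candidate modification sites ("site-
determining" or discriminating ions).

For candidate sites s1 < ... < sk, a b-type ion cleaved in the span between
s_j and s_{j+1} contains the modification of exactly the members modified at
a site <= s_j.  With h(.) the smoothed MS2 XIC height at the MS1 apex,

    F_j = sum_span h(modified variant) / sum_span [h(modified) + h(unmodified)]

estimates the cumulative fraction of signal from those members; y-type ions
in the same span estimate 1 - F_j and the two are averaged.  Member
fractions are the first differences of F (with F_0 = 0, F_k = 1), clipped to
be nonnegative and renormalized to sum to one.  An alternative nonnegative
least-squares fit over the full ion-membership matrix is available as
``method="nnls"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _nnls

from .chemistry import (
    ModifiedPeptideForm,
    fragment_mz_series,
    isotope_envelope,
    monoisotopic_mass,
    precursor_mz,
)
from .dia import DIARun
from .targets import IsomerGroup

logger = logging.getLogger(__name__)

__all__ = [
    "XICTrace",
    "ChromPeak",
    "PeakQuantRecord",
    "IsomerSplitResult",
    "extract_xic",
    "detect_peak",
    "quantify_form",
    "discriminating_ions",
    "split_isobaric",
    "calibrate_rt",
    "quantify_run",
]


@dataclass
class XICTrace:
    """Extracted ion chromatogram for one target m/z at a ppm tolerance."""

    mz: float
    ppm: float
    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.shape != self.intensity.shape:
            raise ValueError("rt/intensity length mismatch")
        if self.rt.size > 1 and np.any(np.diff(self.rt) <= 0):
            raise ValueError("XIC retention times must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("negative XIC intensity")

    def smoothed(self) -> np.ndarray:
        return _smooth3(self.intensity)

    def value_at(self, rt: float, smoothed: bool = True) -> float:
        """Trace value at the sample nearest to ``rt``."""
        if self.rt.size == 0:
            return 0.0
        i = int(np.argmin(np.abs(self.rt - rt)))
        return float(self.smoothed()[i] if smoothed else self.intensity[i])


def _smooth3(y: np.ndarray) -> np.ndarray:
    """3-point moving average; edges average the available neighbors."""
    if y.size < 3:
        return y.astype(float).copy()
    out = np.convolve(y, np.ones(3), mode="same")
    counts = np.convolve(np.ones_like(y), np.ones(3), mode="same")
    return out / counts


@dataclass
class ChromPeak:
    """One integrated chromatographic peak."""

    apex_rt: float
    left_rt: float
    right_rt: float
    area: float          # trapezoidal, intensity x minutes
    height: float        # raw apex intensity
    points: int          # samples between the boundaries, inclusive
    apex_index: int = 0
    left_index: int = 0
    right_index: int = 0

    def __post_init__(self) -> None:
        if not (self.left_rt < self.apex_rt < self.right_rt):
            raise ValueError("peak boundaries must bracket the apex")
        if self.area < 0 or self.points < 1:
            raise ValueError("invalid peak geometry")

    @property
    def width_min(self) -> float:
        return self.right_rt - self.left_rt


@dataclass
class PeakQuantRecord:
    """Per-form quantification result (post isomer splitting)."""

    label: str
    protein: str
    span: tuple[int, int]
    charge: int
    detected: bool
    apex_rt: float = np.nan
    left_rt: float = np.nan
    right_rt: float = np.nan
    area: float = 0.0
    points: int = 0
    isomer_fraction: float = 1.0
    ratio: float = np.nan
    flags: tuple[str, ...] = ()


@dataclass
class IsomerSplitResult:
    """Outcome of the fragment-based split of one isobaric group."""

    group: IsomerGroup
    fractions: dict[str, float]
    cumulative: np.ndarray
    ions_used: list[dict]
    low_confidence: bool = False

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, not 1")
        if any(not (0.0 <= f <= 1.0) for f in self.fractions.values()):
            raise ValueError("fractions outside [0, 1]")


# ---------------------------------------------------------------------------
# XIC extraction and peak detection
# ---------------------------------------------------------------------------

def extract_xic(
    run: DIARun,
    mz: float,
    ppm: float = 10.0,
    ms_level: int = 1,
    window: tuple[float, float] | float | None = None,
) -> XICTrace:
    """Per-spectrum sum of intensities within |dm/z|/mz <= ppm x 1e-6.

    For MS2 the isolation ``window`` selects the DIA trace; it may be given
    as explicit (low, high) bounds or as a precursor m/z, in which case the
    acquired window containing it (center-closest in overlaps) is used.
    """
    if ms_level == 1:
        spectra = run.ms1_spectra()
    else:
        if window is None:
            raise ValueError("MS2 XIC extraction requires an isolation window")
        if not isinstance(window, tuple):
            window = run.window_for(float(window))
        spectra = run.ms2_spectra(window)
    tol = mz * ppm * 1e-6
    rts = np.empty(len(spectra))
    vals = np.empty(len(spectra))
    for i, s in enumerate(spectra):
        rts[i] = s.rt_min
        lo = np.searchsorted(s.mz, mz - tol, side="left")
        hi = np.searchsorted(s.mz, mz + tol, side="right")
        vals[i] = s.intensity[lo:hi].sum() if hi > lo else 0.0
    return XICTrace(mz=mz, ppm=ppm, rt=rts, intensity=vals)


def sum_traces(traces: Sequence[XICTrace]) -> XICTrace:
    """Element-wise sum of XICs sampled on the same RT grid."""
    base = traces[0]
    total = np.zeros_like(base.intensity)
    for t in traces:
        if t.rt.shape != base.rt.shape or np.any(np.abs(t.rt - base.rt) > 1e-9):
            raise ValueError("traces are not on a common RT grid")
        total += t.intensity
    return XICTrace(mz=base.mz, ppm=base.ppm, rt=base.rt, intensity=total)


def detect_peak(
    trace: XICTrace,
    expected_rt: float,
    rt_tolerance: float,
    rel_boundary: float = 0.01,
    noise_floor: float = 0.0,
) -> ChromPeak | None:
    """Locate and bound the chromatographic peak nearest the expected RT.

    The trace is smoothed with a 3-point moving average; candidate apexes
    are smoothed local maxima within expected_rt +/- rt_tolerance; the
    chosen apex maximizes smoothed intensity (ties resolved toward the
    expected RT).  Boundaries extend outward to the first sample below
    ``rel_boundary`` of the apex or to a local valley.  Returns None when no
    candidate clears the noise floor, max(noise_floor, 3 x trace median).
    """
    if trace.rt.size == 0:
        return None
    y = trace.smoothed()
    raw = trace.intensity
    in_window = np.abs(trace.rt - expected_rt) <= rt_tolerance
    floor = max(noise_floor, 3.0 * float(np.median(raw)))

    candidates = []
    for i in np.nonzero(in_window)[0]:
        left_ok = i == 0 or y[i] >= y[i - 1]
        right_ok = i == y.size - 1 or y[i] >= y[i + 1]
        if left_ok and right_ok and y[i] > 0:
            candidates.append(i)
    if not candidates:
        return None
    apex = min(
        candidates,
        key=lambda i: (-y[i], abs(trace.rt[i] - expected_rt)),
    )
    if y[apex] < floor or y[apex] <= 0:
        return None

    thr = rel_boundary * y[apex]
    left = apex
    while left > 0:
        if y[left - 1] > y[left]:  # local valley
            break
        left -= 1
        if y[left] < thr:
            break
    right = apex
    while right < y.size - 1:
        if y[right + 1] > y[right]:
            break
        right += 1
        if y[right] < thr:
            break
    if left == apex or right == apex:
        return None  # truncated at the trace edge; unusable
    area = float(np.trapezoid(raw[left : right + 1], trace.rt[left : right + 1]))
    return ChromPeak(
        apex_rt=float(trace.rt[apex]),
        left_rt=float(trace.rt[left]),
        right_rt=float(trace.rt[right]),
        area=area,
        height=float(raw[apex]),
        points=int(right - left + 1),
        apex_index=int(apex),
        left_index=int(left),
        right_index=int(right),
    )


def quantify_form(
    run: DIARun,
    form: ModifiedPeptideForm,
    charge: int,
    expected_rt: float,
    rt_tolerance: float = 0.3,
    ppm: float = 10.0,
    n_isotopes: int = 3,
    noise_floor: float = 0.0,
) -> tuple[PeakQuantRecord, ChromPeak | None]:
    """MS1 quantification of one form: the peak is detected on the summed
    isotope-cluster XIC and each of the first ``n_isotopes`` isotopologue
    XICs is integrated over the shared boundaries."""
    env = isotope_envelope(form, charge, n_peaks=n_isotopes)
    traces = [extract_xic(run, m, ppm=ppm, ms_level=1) for m in env.mz]
    cluster = sum_traces(traces)
    peak = detect_peak(
        cluster, expected_rt, rt_tolerance, noise_floor=noise_floor
    )
    if peak is None:
        rec = PeakQuantRecord(
            label=form.label,
            protein=form.protein,
            span=form.span,
            charge=charge,
            detected=False,
            flags=("not_detected",),
        )
        return rec, None
    lo, hi = peak.left_index, peak.right_index
    area = sum(
        float(np.trapezoid(t.intensity[lo : hi + 1], t.rt[lo : hi + 1]))
        for t in traces
    )
    rec = PeakQuantRecord(
        label=form.label,
        protein=form.protein,
        span=form.span,
        charge=charge,
        detected=True,
        apex_rt=peak.apex_rt,
        left_rt=peak.left_rt,
        right_rt=peak.right_rt,
        area=area,
        points=peak.points,
    )
    return rec, peak


# ---------------------------------------------------------------------------
# discriminating ions and isobaric splitting
# ---------------------------------------------------------------------------

def _member_fragments(group: IsomerGroup, product_charge: int = 1):
    return [
        dict(fragment_mz_series(f, ion_types=("b", "y"), product_charge=product_charge))
        for f in group.forms
    ]


def discriminating_ions(
    group: IsomerGroup, product_charge: int = 1, decimals: int = 4
) -> dict[str, list[tuple[str, float]]]:
    """Per-member fragment ions whose m/z differs between group members.

    Returns {form label: [(ion label, that member's m/z), ...]}.  An ion is
    discriminating when at least two members disagree on its m/z; for
    positional isomers these are exactly the ions cleaved between two
    candidate modification sites.
    """
    frags = _member_fragments(group, product_charge)
    out: dict[str, list[tuple[str, float]]] = {f.label: [] for f in group.forms}
    if len(group.forms) < 2:
        return out
    for ion in frags[0]:
        values = [round(fr[ion], decimals) for fr in frags]
        if len(set(values)) > 1:
            for form, fr in zip(group.forms, frags):
                out[form.label].append((ion, fr[ion]))
    return out


def _member_sites(group: IsomerGroup) -> list[int] | None:
    """Map each member to the single candidate site that sets it apart.

    Works for groups of single-site positional isomers (each member differs
    from the consensus at exactly one candidate site); returns None when the
    pattern is more complex.
    """
    sites = group.candidate_sites
    assigned = []
    for f in group.forms:
        own = [
            pos
            for pos in sites
            if any(m.name != "prop" for m in f.mods_at(pos))
        ]
        if len(own) != 1:
            return None
        assigned.append(own[0])
    if len(set(assigned)) != len(assigned):
        return None
    return assigned


def _span_cleavages(sites: list[int], j: int, n_res: int) -> range:
    """Cleavage positions between candidate sites j and j+1 (1-based)."""
    return range(sites[j - 1], min(sites[j], n_res))


def split_isobaric(
    group: IsomerGroup,
    run: DIARun,
    ms1_peak: ChromPeak,
    ppm_ms2: float = 20.0,
    method: str = "spans",
    product_charge: int = 1,
) -> IsomerSplitResult:
    """Split a co-eluting isobaric group by discriminating MS2 fragment ions.

    Heights are smoothed MS2 XIC values at the MS1 apex retention time, read
    from the DIA window that isolates the shared precursor.  See the module
    docstring for the linear-equation formulation; ``method="nnls"`` instead
    solves the nonnegative least-squares system over the full ion-membership
    matrix.  When no discriminating ion carries signal the split falls back
    to uniform fractions and is flagged low-confidence.
    """
    n_members = len(group.forms)
    if n_members < 2:
        raise ValueError("isomer splitting needs at least two members")
    precursor = precursor_mz(monoisotopic_mass(group.forms[0]), group.charge)
    window = run.window_for(precursor)
    frags = _member_fragments(group, product_charge)
    apex_rt = ms1_peak.apex_rt

    def height(mz: float) -> float:
        trace = extract_xic(run, mz, ppm=ppm_ms2, ms_level=2, window=window)
        return trace.value_at(apex_rt, smoothed=True)

    sites = _member_sites(group)
    if method == "spans" and sites is None:
        logger.warning(
            "group %s is not a single-site isomer family; using nnls",
            group.forms[0].label,
        )
        method = "nnls"

    if method == "spans":
        return _split_spans(group, frags, sites, height)
    if method == "nnls":
        return _split_nnls(group, frags, height)
    raise ValueError(f"unknown split method: {method!r}")


def _order_by_site(group: IsomerGroup, member_sites: list[int]):
    order = np.argsort(member_sites, kind="stable")
    return order, [member_sites[i] for i in order]


def _split_spans(
    group: IsomerGroup,
    frags: list[dict],
    member_sites: list[int],
    height: Callable[[float], float],
) -> IsomerSplitResult:
    n_res = len(group.sequence)
    order, sites = _order_by_site(group, member_sites)
    k = len(sites)
    cumulative = np.full(k - 1, np.nan)
    ions_used: list[dict] = []

    for j in range(1, k):
        estimates = []
        for ion_type in ("b", "y"):
            s_mod = s_tot = 0.0
            seen = False
            for c in _span_cleavages(sites, j, n_res):
                invert = ion_type == "y"
                ion = f"y{n_res - c}" if invert else f"b{c}"
                values = [round(fr[ion], 4) for fr in frags]
                if len(set(values)) != 2:
                    continue  # needs exactly a modified/unmodified variant pair
                # members with site <= s_{j-1} come first in site order; for a
                # b ion they carry the modification inside the fragment, for a
                # y ion it is the members with site > s_{j-1}
                low = {values[i] for i in order[:j]}
                high = {values[i] for i in order[j:]}
                if len(low) != 1 or len(high) != 1 or low == high:
                    continue
                mz_mod = frags[order[j] if invert else order[0]][ion]
                mz_unmod = frags[order[0] if invert else order[j]][ion]
                h_mod = height(mz_mod)
                h_unmod = height(mz_unmod)
                s_mod += h_mod
                s_tot += h_mod + h_unmod
                seen = True
                ions_used.append(
                    {
                        "span": j,
                        "ion": ion,
                        "mz_modified": mz_mod,
                        "mz_unmodified": mz_unmod,
                        "h_modified": h_mod,
                        "h_unmodified": h_unmod,
                    }
                )
            if seen and s_tot > 0:
                share = s_mod / s_tot
                estimates.append(1.0 - share if ion_type == "y" else share)
        if estimates:
            cumulative[j - 1] = float(np.mean(estimates))

    low_confidence = bool(np.any(np.isnan(cumulative)))
    full = np.concatenate([[0.0], cumulative, [1.0]])
    if np.all(np.isnan(cumulative)):
        fractions = np.full(k, 1.0 / k)
    else:
        idx = np.arange(full.size)
        known = ~np.isnan(full)
        full = np.interp(idx, idx[known], full[known])
        fractions = np.clip(np.diff(full), 0.0, None)
        total = fractions.sum()
        if total <= 0:
            fractions = np.full(k, 1.0 / k)
            low_confidence = True
        else:
            fractions = fractions / total

    labels = [group.forms[i].label for i in order]
    mapping = dict(zip(labels, (float(x) for x in fractions)))
    return IsomerSplitResult(
        group=group,
        fractions={f.label: mapping[f.label] for f in group.forms},
        cumulative=full[1:-1],
        ions_used=ions_used,
        low_confidence=low_confidence,
    )


def _split_nnls(
    group: IsomerGroup,
    frags: list[dict],
    height: Callable[[float], float],
) -> IsomerSplitResult:
    n = len(group.forms)
    rows: list[np.ndarray] = []
    obs: list[float] = []
    ions_used: list[dict] = []
    for ion in frags[0]:
        values = [round(fr[ion], 4) for fr in frags]
        variants = sorted(set(values))
        if len(variants) < 2:
            continue
        heights = {v: height(fr[ion]) for v, fr in zip(values, frags)}
        total = sum(heights[v] for v in variants)
        if total <= 0:
            continue
        for v in variants:
            members = np.array([1.0 if val == v else 0.0 for val in values])
            rows.append(members)
            obs.append(heights[v] / total)
            ions_used.append(
                {"ion": ion, "mz": v, "height": heights[v], "share": obs[-1]}
            )
    if not rows:
        return IsomerSplitResult(
            group=group,
            fractions={f.label: 1.0 / n for f in group.forms},
            cumulative=np.array([]),
            ions_used=[],
            low_confidence=True,
        )
    a = np.vstack(rows)
    x, _ = _nnls(a, np.array(obs))
    total = x.sum()
    fractions = x / total if total > 0 else np.full(n, 1.0 / n)
    return IsomerSplitResult(
        group=group,
        fractions={f.label: float(v) for f, v in zip(group.forms, fractions)},
        cumulative=np.array([]),
        ions_used=ions_used,
        low_confidence=total <= 0,
    )


# ---------------------------------------------------------------------------
# retention-time calibration and run-level quantification
# ---------------------------------------------------------------------------

def calibrate_rt(
    run: DIARun,
    anchors: Sequence[tuple[float, float]],
    ppm: float = 10.0,
) -> Callable[[float], float]:
    """Monotone (linear) map from library RT to observed RT.

    Each anchor (m/z, library RT) is located by the global maximum of its
    MS1 XIC; a least-squares line through (library, observed) pairs is
    returned, or the identity when fewer than two usable anchors exist.
    """
    lib, obs = [], []
    for mz, lib_rt in anchors:
        trace = extract_xic(run, mz, ppm=ppm, ms_level=1)
        if trace.intensity.size == 0 or trace.intensity.max() <= 0:
            continue
        lib.append(lib_rt)
        obs.append(float(trace.rt[int(np.argmax(trace.intensity))]))
    if len(lib) < 2 or np.ptp(lib) == 0:
        return lambda rt: rt
    slope, intercept = np.polyfit(lib, obs, 1)
    if slope <= 0:
        logger.warning("non-monotone RT calibration fit; falling back to identity")
        return lambda rt: rt
    return lambda rt: slope * rt + intercept


def quantify_run(
    run: DIARun,
    table: pd.DataFrame,
    registry=None,
    ppm_ms1: float = 10.0,
    ppm_ms2: float = 20.0,
    rt_tolerance: float = 0.3,
    n_isotopes: int = 3,
    split_method: str = "spans",
    split_isomers: bool = True,
    calibration: Callable[[float], float] | None = None,
    group_ppm: float | None = None,
    noise_floor: float = 0.0,
) -> pd.DataFrame:
    """Quantify every target in a form table against one DIA run.

    The table must carry the target-database columns plus ``charge`` and
    ``ref_rt``.  Isobaric members are grouped per backbone and charge,
    quantified from the shared MS1 isotope cluster, and split by MS2
    discriminating ions; per-region peptide ratios are appended.
    """
    from .qc import peptide_ratio
    from .targets import forms_from_table, group_isobaric

    if table.empty:
        logger.warning("empty target table; nothing to quantify")
        return pd.DataFrame(
            columns=[
                "label", "protein", "span_start", "span_end", "charge",
                "detected", "apex_rt", "left_rt", "right_rt", "area",
                "points", "isomer_fraction", "low_confidence", "ratio",
            ]
        )
    if calibration is None:
        calibration = lambda rt: rt
    forms = forms_from_table(table, registry)
    charges = table["charge"].astype(int).to_numpy()
    ref_rts = table["ref_rt"].astype(float).to_numpy()
    info = {
        id(f): (z, rt) for f, z, rt in zip(forms, charges, ref_rts)
    }

    records: list[dict] = []
    by_key: dict[tuple, list[ModifiedPeptideForm]] = {}
    for f in forms:
        z, _ = info[id(f)]
        by_key.setdefault((f.protein, f.span, f.sequence, z), []).append(f)

    for (protein, span, seq, charge), members in sorted(
        by_key.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][3])
    ):
        groups = group_isobaric(members, charge, ppm_tol=group_ppm or ppm_ms1)
        for grp in groups:
            expected = calibration(
                float(np.mean([info[id(f)][1] for f in grp.forms]))
            )
            rec, peak = quantify_form(
                run,
                grp.forms[0],
                charge,
                expected,
                rt_tolerance=rt_tolerance,
                ppm=ppm_ms1,
                n_isotopes=n_isotopes,
                noise_floor=noise_floor,
            )
            if len(grp) == 1:
                records.append(_record_row(grp.forms[0], charge, rec, 1.0, rec.flags))
                continue
            if peak is None or not split_isomers:
                share = np.nan if peak is None else 1.0 / len(grp)
                for f in grp.forms:
                    flags = rec.flags if peak is None else rec.flags + ("unsplit",)
                    frac = 0.0 if peak is None else 1.0 / len(grp)
                    row = _record_row(f, charge, rec, frac, flags)
                    row["area"] = rec.area * frac if peak is not None else 0.0
                    records.append(row)
                continue
            split = split_isobaric(
                grp, run, peak, ppm_ms2=ppm_ms2, method=split_method
            )
            for f in grp.forms:
                frac = split.fractions[f.label]
                flags = rec.flags + (("low_confidence",) if split.low_confidence else ())
                row = _record_row(f, charge, rec, frac, flags)
                row["area"] = rec.area * frac
                records.append(row)

    df = pd.DataFrame(records)
    return peptide_ratio(df)


def _record_row(
    form: ModifiedPeptideForm,
    charge: int,
    rec: PeakQuantRecord,
    fraction: float,
    flags: tuple[str, ...],
) -> dict:
    return {
        "label": form.label,
        "protein": form.protein,
        "span_start": form.span[0],
        "span_end": form.span[1],
        "charge": charge,
        "detected": rec.detected,
        "apex_rt": rec.apex_rt,
        "left_rt": rec.left_rt,
        "right_rt": rec.right_rt,
        "area": rec.area,
        "points": rec.points,
        "isomer_fraction": fraction,
        "low_confidence": "low_confidence" in flags,
        "flags": ";".join(flags),
    }
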