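"""Synthetic DIA runs with known ground truth.

The simulator emits the same cycle structure the quant engine consumes: at a
fixed cadence over the gradient, one MS1 spectrum followed by one MS2
spectrum per isolation window.  Each target form elutes as a Gaussian; its
MS1 signal is the first-3-isotope envelope scaled by the elution profile
(normalized so the trapezoid-integrated cluster area equals the injected
area), and every DIA window containing the precursor receives the form's
b/y fragments, with per-ion base intensities drawn once per backbone so that
discriminating ions are non-degenerate and co-eluting isomer groups mix
according to the injected fractions.  Optional noise is multiplicative
log-normal per peak plus a uniform additive floor; replicates apply a
proportional retention-time jitter.  Everything is reproducible from seeds.

What this emulates: the acquisition geometry (cycle time, windows), isotope
clusters, co-eluting positional isomers, pseudo-isobaric neighbors, and
benign intensity noise.  What it does not: chimeric background proteome,
charge envelopes beyond the configured charge, detector saturation, or
chromatographic tailing — recovery results bound what the engine can do on
well-behaved signals, not on arbitrary real data.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .chemistry import (
    ModifiedPeptideForm,
    fragment_mz_series,
    isotope_envelope,
    monoisotopic_mass,
    precursor_mz,
)
from .dia import DIARun, Spectrum
from .targets import digest, enumerate_forms, load_histones
from .windows import WindowScheme, cycle_time, variable_scheme

__all__ = ["FormTruth", "SyntheticTruth", "simulate_run", "simulate_replicates",
           "default_histone_truth", "truth_table"]


@dataclass
class FormTruth:
    """Ground truth for one form: where it elutes and how much of it there is."""

    form: ModifiedPeptideForm
    charge: int
    rt_min: float
    sigma_s: float
    area: float                 # total MS1 isotope-cluster area, intensity x min
    group_id: str | None = None
    fraction: float = 1.0       # share within its isomer group

    @property
    def label(self) -> str:
        return self.form.label


@dataclass
class SyntheticTruth:
    """Run-level specification: forms, acquisition scheme and noise model."""

    forms: list[FormTruth]
    scheme: WindowScheme
    gradient_min: float = 10.0
    noise_sigma: float = 0.0        # log-normal multiplicative sigma
    noise_floor: float = 0.0        # uniform additive intensity per peak
    rt_jitter_frac: float = 0.01    # proportional RT jitter between replicates
    seed: int = 0

    def __post_init__(self) -> None:
        for ft in self.forms:
            if ft.sigma_s <= 0:
                raise ValueError(f"{ft.label}: sigma must be positive")
            if not (0 <= ft.rt_min <= self.gradient_min):
                raise ValueError(f"{ft.label}: RT outside the gradient")
        by_group: dict[str, float] = {}
        for ft in self.forms:
            if ft.group_id is not None:
                by_group[ft.group_id] = by_group.get(ft.group_id, 0.0) + ft.fraction
        for gid, total in by_group.items():
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"group {gid}: fractions sum to {total}")

    @property
    def cycle_time_s(self) -> float:
        return cycle_time(self.scheme)


def _fragment_base_intensities(truth: SyntheticTruth) -> dict:
    """Per-(backbone, ion label) relative base intensity, uniform(0.2, 1).

    Drawn from the truth seed only — fragment propensities are molecular
    properties, so they are identical across replicates and noise seeds.
    """
    rng = np.random.default_rng([truth.seed % (2**31), 911])
    out: dict = {}
    for ft in truth.forms:
        backbone = (ft.form.protein, ft.form.span)
        for ion, _ in fragment_mz_series(ft.form):
            key = (backbone, ion)
            if key not in out:
                out[key] = rng.uniform(0.2, 1.0)
    return out


def simulate_run(
    truth: SyntheticTruth,
    seed: int | None = None,
    rt_shift: dict[str, float] | None = None,
) -> DIARun:
    """Forward-simulate one DIA run from a truth specification.

    ``seed`` controls the noise realization (defaults to the truth seed);
    ``rt_shift`` optionally maps form labels to RT offsets in minutes (used
    by :func:`simulate_replicates` for jitter).  Precursors outside every
    isolation window are skipped in MS2 with a warning.
    """
    import logging

    logger = logging.getLogger(__name__)
    rng = np.random.default_rng([(seed if seed is not None else truth.seed) % (2**31), 7])
    betas = _fragment_base_intensities(truth)
    ct_min = truth.cycle_time_s / 60.0
    n_cycles = int(np.floor(truth.gradient_min / ct_min))
    windows = truth.scheme.windows
    n_windows = len(windows)
    scan_dt = ct_min / (n_windows + 1)

    # precompute per-form static spectra ingredients
    prepared = []
    for ft in truth.forms:
        env = isotope_envelope(ft.form, ft.charge, n_peaks=3)
        rel = env.intensity / env.intensity.sum()
        mz0 = precursor_mz(monoisotopic_mass(ft.form), ft.charge)
        hits = [i for i, (lo, hi) in enumerate(windows) if lo <= mz0 <= hi]
        if not hits:
            logger.warning("%s: precursor %.3f outside every window; no MS2",
                           ft.label, mz0)
        backbone = (ft.form.protein, ft.form.span)
        frag = [
            (mz, betas[(backbone, ion)])
            for ion, mz in fragment_mz_series(ft.form)
        ]
        shift = (rt_shift or {}).get(ft.label, 0.0)
        prepared.append(
            {
                "ft": ft,
                "rt": ft.rt_min + shift,
                "sigma_min": ft.sigma_s / 60.0,
                "env_mz": env.mz,
                "env_rel": rel,
                "windows": hits,
                "frags": frag,
            }
        )

    spectra: list[Spectrum] = []
    scan = 0
    for c in range(n_cycles):
        t0 = c * ct_min
        active = [
            p for p in prepared
            if abs(t0 - p["rt"]) <= 6.0 * p["sigma_min"] + ct_min
        ]
        # MS1 survey scan
        scan += 1
        mzs, ints = [], []
        for p in active:
            profile = _gauss(t0, p["rt"], p["sigma_min"]) * p["ft"].area
            if profile <= 0:
                continue
            mzs.append(p["env_mz"])
            ints.append(p["env_rel"] * profile)
        spectra.append(
            _make_spectrum(scan, 1, t0, mzs, ints, rng,
                           truth.noise_sigma, truth.noise_floor)
        )
        # MS2 window scans, fixed order
        for w, (lo, hi) in enumerate(windows):
            scan += 1
            t = t0 + (w + 1) * scan_dt
            mzs, ints = [], []
            for p in active:
                if w not in p["windows"]:
                    continue
                profile = _gauss(t, p["rt"], p["sigma_min"]) * p["ft"].area
                if profile <= 0:
                    continue
                fr = np.array([f[0] for f in p["frags"]])
                amp = np.array([f[1] for f in p["frags"]]) * 0.5 * profile
                mzs.append(fr)
                ints.append(amp)
            spectra.append(
                Spectrum(
                    scan=scan,
                    ms_level=2,
                    rt_min=t,
                    window=(lo, hi),
                    precursor_mz=(lo + hi) / 2,
                    **_merge_peaks(mzs, ints, rng, truth.noise_sigma,
                                   truth.noise_floor),
                )
            )
    return DIARun(
        spectra,
        metadata={
            "cycle_time_s": truth.cycle_time_s,
            "n_cycles": n_cycles,
            "synthetic": True,
        },
    )


def _gauss(t: float, mu: float, sigma_min: float) -> float:
    z = (t - mu) / sigma_min
    if abs(z) > 6.0:
        return 0.0
    return float(np.exp(-0.5 * z * z) / (sigma_min * np.sqrt(2.0 * np.pi)))


def _merge_peaks(mzs, ints, rng, noise_sigma, noise_floor) -> dict:
    if not mzs:
        return {"mz": np.array([]), "intensity": np.array([])}
    # 5-dp canonical m/z grid: co-isolated isomers produce the same fragment
    # via different float paths; a centroider would report one peak
    mz = np.round(np.concatenate(mzs), 5)
    inten = np.concatenate(ints)
    uniq, inverse = np.unique(mz, return_inverse=True)
    summed = np.zeros_like(uniq)
    np.add.at(summed, inverse, inten)
    if noise_sigma > 0:
        summed = summed * np.exp(rng.normal(0.0, noise_sigma, summed.size))
    if noise_floor > 0:
        summed = summed + rng.uniform(0.0, noise_floor, summed.size)
    return {"mz": uniq, "intensity": summed}


def _make_spectrum(scan, level, rt, mzs, ints, rng, noise_sigma, noise_floor):
    return Spectrum(
        scan=scan,
        ms_level=level,
        rt_min=rt,
        **_merge_peaks(mzs, ints, rng, noise_sigma, noise_floor),
    )


def simulate_replicates(
    truth: SyntheticTruth, n_replicates: int, seed: int | None = None
) -> list[DIARun]:
    """Simulate jittered replicate runs: per replicate and form the RT is
    shifted by a proportional normal deviate of sd ``rt_jitter_frac``."""
    base = seed if seed is not None else truth.seed
    runs = []
    for r in range(n_replicates):
        rng = np.random.default_rng([base % (2**31), 31, r])
        # one deviate per chromatographic entity: isomer-group members share
        # a peptide backbone and so shift together between runs
        entities = sorted({ft.group_id or ft.label for ft in truth.forms})
        deviates = dict(zip(entities, rng.normal(0.0, truth.rt_jitter_frac, len(entities))))
        shift = {
            ft.label: float(deviates[ft.group_id or ft.label] * ft.rt_min)
            for ft in truth.forms
        }
        runs.append(simulate_run(truth, seed=base + 1000 * (r + 1), rt_shift=shift))
    return runs


# ---------------------------------------------------------------------------
# the bundled default truth
# ---------------------------------------------------------------------------

def default_histone_truth(
    seed: int = 0,
    noise_sigma: float = 0.0,
    noise_floor: float = 0.0,
    rt_jitter_frac: float = 0.01,
    gradient_min: float = 10.0,
    n_windows: int = 42,
    sigma_s: float = 1.25,
) -> SyntheticTruth:
    """A realistic histone-like truth: >=30 derivatized forms from the
    bundled H3/H4/H2A sequences with precursors spanning ~m/z 300-900 on a
    10-min gradient, including the H4 4-17 mono-acetyl quartet at fractions
    (0.4, 0.3, 0.2, 0.1) and an H3K27 me3/ac pseudo-isobaric pair.

    The 1.25-s Gaussian sigma gives ~7.6-s peak bases, and the default
    42-window variable scheme with 100/10 ms accumulations reproduces the
    0.761-s cycle.
    """
    proteins = load_histones()
    peptides = {
        (p.protein, p.span): p
        for name in ("H3", "H4", "H2A")
        for p in digest(proteins[name], protein=name)
    }

    entries: list[tuple] = []  # (forms, group_id, fractions, area)

    def pep(protein, start, end):
        return peptides[(protein, (start, end))]

    # H4 4-17 GKGGKGLGKGGAKR: unmodified + the mono-acetyl quartet
    h4_tail = pep("H4", 4, 17)
    entries.append((enumerate_forms(h4_tail, {}), None, None, 3.0e6))
    quartet = enumerate_forms(h4_tail, {"K": ["ac"]}, max_mods=1)
    entries.append((quartet, "H4_4-17_ac", (0.4, 0.3, 0.2, 0.1), 2.0e6))

    # H3 27-40 KSAPATGGVKKPHR: K27 marks incl. the me3/ac pseudo-isobaric pair
    h3_27 = pep("H3", 27, 40)
    entries.append((enumerate_forms(h3_27, {}), None, None, 2.5e6))
    for modname, area in (("me3", 1.5e6), ("ac", 0.9e6), ("me1", 1.1e6)):
        f = [
            x
            for x in enumerate_forms(h3_27, {"K": [modname]}, max_mods=1)
            if any(m.name == modname for m in x.mods_at(1))  # the K27 form
        ]
        entries.append((f[:1], None, None, area))

    # H3 9-17 KSTGGKAPR: K9/K14 marks, one 2-member mono-ac group
    h3_9 = pep("H3", 9, 17)
    entries.append((enumerate_forms(h3_9, {}), None, None, 2.2e6))
    entries.append(
        (enumerate_forms(h3_9, {"K": ["ac"]}, max_mods=1), "H3_9-17_ac", (0.65, 0.35), 1.2e6)
    )
    entries.append(
        ([enumerate_forms(h3_9, {"K": ["me3"]}, max_mods=1)[0]], None, None, 1.4e6)
    )

    # H3 18-26 KQLATKAAR: K18/K23 mono-ac pair
    h3_18 = pep("H3", 18, 26)
    entries.append((enumerate_forms(h3_18, {}), None, None, 2.0e6))
    entries.append(
        (enumerate_forms(h3_18, {"K": ["ac"]}, max_mods=1), "H3_18-26_ac", (0.55, 0.45), 1.0e6)
    )

    # H3 3-8 TKQTAR: K4 methylation states
    h3_3 = pep("H3", 3, 8)
    entries.append((enumerate_forms(h3_3, {}), None, None, 1.8e6))
    for modname, area in (("me1", 0.8e6), ("me3", 0.6e6)):
        entries.append(
            (enumerate_forms(h3_3, {"K": [modname]}, max_mods=1), None, None, area)
        )

    # H4 20-23 KVLR: K20 methylation states
    h4_20 = pep("H4", 20, 23)
    entries.append((enumerate_forms(h4_20, {}), None, None, 2.4e6))
    for modname, area in (("me1", 1.3e6), ("me2", 1.6e6), ("me3", 0.7e6)):
        entries.append(
            (enumerate_forms(h4_20, {"K": [modname]}, max_mods=1), None, None, area)
        )

    # H2A 4-11 GKQGGKAR: K5/K9 mono-ac pair
    h2a_4 = pep("H2A", 4, 11)
    entries.append((enumerate_forms(h2a_4, {}), None, None, 1.6e6))
    entries.append(
        (enumerate_forms(h2a_4, {"K": ["ac"]}, max_mods=1), "H2A_4-11_ac", (0.7, 0.3), 0.9e6)
    )

    # unmodified singleton backbones to fill out the m/z range
    for protein, start, end, area in (
        ("H4", 24, 35, 2.1e6),
        ("H4", 46, 55, 1.9e6),
        ("H4", 56, 67, 1.7e6),
        ("H4", 68, 78, 1.5e6),
        ("H4", 79, 92, 1.3e6),
        ("H3", 41, 49, 1.2e6),
        ("H3", 73, 83, 1.0e6),
    ):
        entries.append((enumerate_forms(pep(protein, start, end), {}), None, None, area))

    # choose a charge placing each precursor inside ~m/z 300-900
    def pick_charge(form) -> int:
        mass = monoisotopic_mass(form)
        for z in (2, 3, 4):
            if 300.0 <= precursor_mz(mass, z) <= 900.0:
                return z
        return 2

    forms: list[FormTruth] = []
    rt_slot = 0
    # elution slots span the middle of the gradient (13%..90% for the
    # default 10-min run) and compress proportionally for shorter gradients
    rt_first, rt_step = 1.3 * gradient_min / 10.0, 0.24 * gradient_min / 10.0
    for group_forms, group_id, fractions, area in entries:
        rt = rt_first + rt_slot * rt_step
        rt_slot += 1
        if group_id is None:
            for f in group_forms:
                forms.append(
                    FormTruth(
                        form=f,
                        charge=pick_charge(f),
                        rt_min=rt,
                        sigma_s=sigma_s,
                        area=area,
                    )
                )
        else:
            charge = pick_charge(group_forms[0])
            for f, frac in zip(group_forms, fractions):
                forms.append(
                    FormTruth(
                        form=f,
                        charge=charge,
                        rt_min=rt,
                        sigma_s=sigma_s,
                        area=area * frac,
                        group_id=group_id,
                        fraction=frac,
                    )
                )

    target_mzs = [
        precursor_mz(monoisotopic_mass(ft.form), ft.charge) for ft in forms
    ]
    scheme = variable_scheme(
        target_mzs,
        n_windows=n_windows,
        min_width=5.0,
        overlap=1.0,
        mz_range=(299.0, 901.0),
        ms1_ms=100.0,
        ms2_ms=10.0,
        overhead_ms=5.6,
    )
    return SyntheticTruth(
        forms=forms,
        scheme=scheme,
        gradient_min=gradient_min,
        noise_sigma=noise_sigma,
        noise_floor=noise_floor,
        rt_jitter_frac=rt_jitter_frac,
        seed=seed,
    )


def truth_table(truth: SyntheticTruth) -> pd.DataFrame:
    """Target-database view of a truth (inputs to :func:`quantify_run`)."""
    from .targets import build_target_table

    table = build_target_table([ft.form for ft in truth.forms])
    table["charge"] = [ft.charge for ft in truth.forms]
    table["ref_rt"] = [ft.rt_min for ft in truth.forms]
    table["true_area"] = [ft.area for ft in truth.forms]
    table["group_id"] = [ft.group_id for ft in truth.forms]
    table["true_fraction"] = [ft.fraction for ft in truth.forms]
    return table
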