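"""End-to-end analysis pipeline over an image directory, and the synthetic cohort fixture.

``run`` walks a manifest of micrographs and produces the study's result
tables: per-image morphometry, per-image fractal dimensions, per-image
photometry (opacity, vessels, angiogenesis index), per-group exponential
healing kinetics with fractal time trends, and pairwise comparison
statistics against a reference group.  ``make_fixture`` writes a complete
synthetic cohort (groups x animals x days, left lesioned eyes plus right
control references) with a ground-truth sidecar so the whole pipeline can be
validated against known parameters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fractal as fr
from . import io as pio
from . import kinetics as kin
from . import morphometry as morph
from . import photometry as phot
from . import segmentation as seg
from . import synthetic as syn

log = logging.getLogger("pteryquant")


@dataclass
class RunConfig:
    manifest: Path
    out_dir: Path
    mm_per_px: float = seg.DEFAULT_MM_PER_PX
    window: seg.HSBWindow = field(default_factory=seg.HSBWindow)
    box_sizes: tuple[int, ...] = fr.DEFAULT_BOX_SIZES
    basal_group: str = "HC"
    reference_group: str = "NegCtrl"
    bg_radius_px: int = 50
    seed: int = 0
    log_level: str = "INFO"


@dataclass
class ResultBundle:
    morphometry: pd.DataFrame
    fractal: pd.DataFrame
    photometry: pd.DataFrame
    kinetics: pd.DataFrame
    comparisons: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pio.write_table(out / "morphometry.csv", self.morphometry)
        pio.write_table(out / "fractal.csv", self.fractal)
        pio.write_table(out / "photometry.csv", self.photometry)
        pio.write_table(out / "kinetics.csv", self.kinetics)
        pio.write_table(out / "comparisons.csv", self.comparisons)
        (out / "warnings.log").write_text("".join(w + "\n" for w in self.warnings))


_EMPTY_COLS = {
    "morphometry": ["path", "animal", "group", "day", "eye", *morph.DESCRIPTOR_COLUMNS, "empty"],
    "fractal": ["animal", "group", "day", "afd", "afd_r2", "pfd", "pfd_r2"],
    "photometry": [
        "animal", "group", "day", "lum_left", "lum_right", "delta_opacity",
        "vessel_px", "vessel_um", "ia", "opacity_area_index",
    ],
    "kinetics": [
        "group", "amplitude", "rate", "r2", "n_points",
        "afd_slope", "afd_intercept", "afd_r2", "pfd_slope", "pfd_intercept", "pfd_r2",
    ],
    "comparisons": ["group", "reference", "pct_initial_difference", "rate_slowdown"],
}


def run(config: RunConfig) -> ResultBundle:
    """Run the full analysis described by ``config`` and write all tables."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest = pio.read_manifest(config.manifest)
    warnings_: list[str] = []
    if manifest.empty:
        warnings_.append("empty manifest: nothing to analyze")
        log.warning(warnings_[-1])
        bundle = ResultBundle(*(pd.DataFrame(columns=c) for c in _EMPTY_COLS.values()), warnings_)
        bundle.write(config.out_dir)
        return bundle

    morpho_rows, fractal_rows, photo_rows = [], [], []
    rights: dict[tuple[str, int], int] = {}  # (animal, day) -> red luminosity

    for _, row in manifest[manifest["eye"] == "right"].iterrows():
        try:
            img = _load(row, config.mm_per_px)
            roi = seg.segment_eye_roi(img)
            rights[(row["animal"], row["day"])] = phot.red_luminosity(img, roi)
        except Exception as exc:  # unreadable or unsegmentable frame
            warnings_.append(f"skipped right-eye row {row['path']}: {exc}")
            log.warning(warnings_[-1])

    for _, row in manifest[manifest["eye"] == "left"].iterrows():
        try:
            img = _load(row, config.mm_per_px)
            roi = seg.segment_eye_roi(img)
            lesion = seg.segment_lesion(img, config.window, roi)
            rec = morph.measure(lesion, roi, config.mm_per_px)
            vessels = seg.segment_vessels(img, roi, config.bg_radius_px, lesion_mask=lesion)
            lum_left = phot.red_luminosity(img, roi)
        except Exception as exc:
            warnings_.append(f"skipped row {row['path']}: {exc}")
            log.warning(warnings_[-1])
            continue
        keys = {k: row[k] for k in ("path", "animal", "group", "day", "eye")}
        morpho_rows.append({**keys, **rec.as_dict(), "empty": rec.empty})

        if rec.empty:
            afd = pfd = afd_r2 = pfd_r2 = np.nan
        else:
            est_a = fr.estimate_fractal(lesion, "area", config.box_sizes)
            est_p = fr.estimate_fractal(lesion, "perimeter", config.box_sizes)
            afd, afd_r2, pfd, pfd_r2 = est_a.dimension, est_a.r2, est_p.dimension, est_p.r2
        fractal_rows.append(
            {**{k: keys[k] for k in ("animal", "group", "day")},
             "afd": afd, "afd_r2": afd_r2, "pfd": pfd, "pfd_r2": pfd_r2}
        )

        lum_right = rights.get((row["animal"], row["day"]))
        if lum_right is None:  # fall back to the animal's reference right eye
            cands = [v for (a, _), v in rights.items() if a == row["animal"]]
            lum_right = cands[0] if cands else None
        if lum_right is None:
            warnings_.append(f"missing right eye for animal {row['animal']} day {row['day']}")
            log.warning(warnings_[-1])
        delta = np.nan if lum_right is None else phot.delta_opacity(lum_left, lum_right)
        vpx = int(vessels.sum())
        photo_rows.append(
            {**{k: keys[k] for k in ("animal", "group", "day")},
             "lum_left": lum_left,
             "lum_right": np.nan if lum_right is None else lum_right,
             "delta_opacity": delta,
             "vessel_px": vpx,
             "vessel_um": phot.vessel_um(vpx, config.mm_per_px),
             "ia": np.nan,
             "opacity_area_index": (
                 phot.opacity_area_index(delta, rec.pct_damaged_area)
                 if rec.pct_damaged_area > 0 and np.isfinite(delta)
                 else np.nan
             )}
        )

    morpho = pd.DataFrame(morpho_rows, columns=_EMPTY_COLS["morphometry"])
    fractal_tab = pd.DataFrame(fractal_rows, columns=_EMPTY_COLS["fractal"])
    photo = pd.DataFrame(photo_rows, columns=_EMPTY_COLS["photometry"])
    for tab in (morpho, fractal_tab, photo):
        tab.sort_values([c for c in ("group", "animal", "day") if c in tab.columns],
                        inplace=True, kind="mergesort", ignore_index=True)

    # Angiogenesis index against the basal group's mean vessel extent.
    basal = photo[photo["group"] == config.basal_group]
    if basal.empty or basal["vessel_um"].mean() <= 0:
        warnings_.append(f"basal group {config.basal_group!r} absent or vessel-free; IA not computed")
        log.warning(warnings_[-1])
    else:
        mu_prom = float(basal["vessel_um"].mean())
        photo["ia"] = [phot.angiogenesis_index(v, mu_prom) for v in photo["vessel_um"]]

    kinetics_tab, comparisons = _group_kinetics(morpho, fractal_tab, config, warnings_)

    bundle = ResultBundle(morpho, fractal_tab, photo, kinetics_tab, comparisons, warnings_)
    bundle.write(config.out_dir)
    return bundle


def _load(row: pd.Series, mm_per_px: float) -> seg.CalibratedImage:
    pixels = pio.read_image(row["path"])
    meta = seg.ImageMeta(str(row["animal"]), str(row["group"]), int(row["day"]), str(row["eye"]))
    return seg.CalibratedImage(pixels, mm_per_px, meta)


def _group_kinetics(
    morpho: pd.DataFrame,
    fractal_tab: pd.DataFrame,
    config: RunConfig,
    warnings_: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows, fits = [], {}
    for group, sub in morpho.groupby("group", sort=True):
        day_means = sub.groupby("day")["area_px"].mean()
        fit_row = dict.fromkeys(_EMPTY_COLS["kinetics"][1:], np.nan)
        if len(day_means) >= 3 and (day_means > 0).all():
            fit = kin.fit_exponential_decay(day_means.index, day_means.values)
            fits[group] = fit
            fit_row.update(amplitude=fit.amplitude, rate=fit.rate, r2=fit.r2, n_points=fit.n_points)
        else:
            warnings_.append(f"group {group!r}: no positive lesion series to fit")
        fsub = fractal_tab[fractal_tab["group"] == group].dropna(subset=["afd", "pfd"])
        if fsub["day"].nunique() >= 2:
            for kind in ("afd", "pfd"):
                tr = fr.trend(fsub["day"], fsub[kind])
                fit_row.update({f"{kind}_slope": tr.slope, f"{kind}_intercept": tr.intercept,
                                f"{kind}_r2": tr.r2})
        rows.append({"group": group, **fit_row})
    kinetics_tab = pd.DataFrame(rows, columns=_EMPTY_COLS["kinetics"])

    comp_rows = []
    ref = fits.get(config.reference_group)
    if ref is None:
        warnings_.append(f"reference group {config.reference_group!r} has no fit; no comparisons")
    else:
        for group, fit in sorted(fits.items()):
            if group == config.reference_group:
                continue
            comp_rows.append(
                {"group": group, "reference": config.reference_group,
                 "pct_initial_difference": kin.percent_initial_difference(fit, ref),
                 "rate_slowdown": kin.rate_slowdown(fit, ref)}
            )
    return kinetics_tab, pd.DataFrame(comp_rows, columns=_EMPTY_COLS["comparisons"])


# ---------------------------------------------------------------------------
# Synthetic cohort fixture
# ---------------------------------------------------------------------------

#: Study-condition parameters of the synthetic cohort, one entry per group.
#: Decay rates follow the treatment-study curves (negative control -0.174,
#: dexamethasone -0.100, experimental treatment -0.108 per day); amplitudes
#: are scaled to lesions that fit a 320 x 240 scene.  ``red`` gives the
#: (day-3, day-15) left-eye red-luminosity modes (dexamethasone-like fast
#: opacity recovery, slower recovery in the untreated group); ``vessels`` the
#: per-scene vessel tree length in px; ``irregularity`` the lesion outline
#: roughness (elongated, slow-closing scars in the experimental group get the
#: roughest outlines).
FIXTURE_GROUPS: dict[str, dict] = {
    "HC": dict(amplitude=0.0, rate=0.0, red=(150, 150), vessels=600.0, irregularity=0.0),
    "NegCtrl": dict(amplitude=6000.0, rate=-0.174, red=(110, 122), vessels=1500.0, irregularity=1.2),
    "Dex": dict(amplitude=2000.0, rate=-0.100, red=(118, 146), vessels=1200.0, irregularity=0.6),
    "TxExp": dict(amplitude=1300.0, rate=-0.108, red=(120, 138), vessels=800.0, irregularity=1.5),
}
FIXTURE_DAYS = (3, 7, 10, 15)
RIGHT_EYE_LUM = 150


def make_fixture(
    out_dir: str | Path,
    seed: int = 0,
    n_animals: int = 6,
    days: tuple[int, ...] = FIXTURE_DAYS,
    noise_cv: float = 0.05,
    noise_sd: float = 8.0,
    image_size: tuple[int, int] = (320, 240),
) -> Path:
    """Write a synthetic cohort emulating the study design to ``out_dir``.

    Four groups x ``n_animals`` x ``days`` left-eye images plus one right-eye
    reference image per animal, a manifest CSV, a per-image ground-truth
    sidecar (``truth.csv``), and the generating kinetics parameters
    (``truth_kinetics.json``).  Returns the manifest path.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    w, h = image_size
    center = (h // 2, w // 2)
    radii = (int(h * 0.3125), int(w * 0.3125))
    root = np.random.SeedSequence(seed)
    manifest_rows, truth_rows = [], []

    for gi, (group, spec) in enumerate(FIXTURE_GROUPS.items()):
        if spec["amplitude"] > 0:
            series = syn.generate_decay_series(
                syn.DecaySeriesParams(
                    amplitude=spec["amplitude"], rate=spec["rate"], days=days,
                    replicate_count=n_animals, multiplicative_noise_cv=noise_cv,
                    seed=int(root.spawn(1)[0].generate_state(1)[0] % 2**31),
                )
            )
        else:
            series = [[(d, 0.0) for d in days]] * n_animals
        for ai in range(n_animals):
            animal = f"{group}-{ai + 1:02d}"
            red0, red1 = spec["red"]
            for di, (day, area) in enumerate(series[ai]):
                frac = (day - days[0]) / (days[-1] - days[0])
                scene_seed = int(np.random.SeedSequence([seed, gi, ai, di]).generate_state(1)[0] % 2**31)
                params = syn.EyeSceneParams(
                    image_width=w, image_height=h, eye_center=center, eye_radii=radii,
                    red_luminosity_mode=int(round(red0 + frac * (red1 - red0))),
                    lesion_area_px=float(area), lesion_irregularity=spec["irregularity"],
                    vessel_total_length_px=spec["vessels"], noise_sd=noise_sd, seed=scene_seed,
                )
                image, truth = syn.generate_eye_image(params)
                rel = f"images/{animal}_d{day:02d}_L.png"
                pio.write_image(out / rel, image.pixels)
                manifest_rows.append(dict(path=rel, animal=animal, group=group, day=day, eye="left"))
                truth_rows.append(
                    dict(path=rel, animal=animal, group=group, day=day, eye="left",
                         true_lesion_area_px=truth.true_lesion_area_px,
                         true_vessel_px=truth.true_vessel_px,
                         true_red_mode=truth.true_red_mode)
                )
            # One right-eye reference per animal (healthy contralateral eye).
            scene_seed = int(np.random.SeedSequence([seed, gi, ai, 999]).generate_state(1)[0] % 2**31)
            params = syn.EyeSceneParams(
                image_width=w, image_height=h, eye_center=center, eye_radii=radii,
                red_luminosity_mode=RIGHT_EYE_LUM, lesion_area_px=0.0,
                lesion_irregularity=0.0, vessel_total_length_px=spec["vessels"] * 0.4,
                noise_sd=noise_sd, seed=scene_seed,
            )
            image, truth = syn.generate_eye_image(params)
            rel = f"images/{animal}_ref_R.png"
            pio.write_image(out / rel, image.pixels)
            manifest_rows.append(dict(path=rel, animal=animal, group=group, day=days[0], eye="right"))
            truth_rows.append(
                dict(path=rel, animal=animal, group=group, day=days[0], eye="right",
                     true_lesion_area_px=0, true_vessel_px=truth.true_vessel_px,
                     true_red_mode=truth.true_red_mode)
            )

    manifest_path = out / "manifest.csv"
    pio.write_manifest(manifest_path, pd.DataFrame(manifest_rows))
    pio.write_table(out / "truth.csv", pd.DataFrame(truth_rows))
    (out / "truth_kinetics.json").write_text(
        json.dumps({g: {"amplitude": s["amplitude"], "rate": s["rate"]}
                    for g, s in FIXTURE_GROUPS.items()}, indent=2)
    )
    return manifest_path
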