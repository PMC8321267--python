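"""End-to-end orchestration: generate, prepare, translate, segment, score.

A single :class:`PipelineConfig` drives the full experiment: a
synthetic two-domain dataset is generated, the dermoscopic images are
(optionally) dark-corner cropped, the translator is trained on the
train subsets, the dermoscopic training set (Set D) is translated into
the macroscopic domain (Set M_artificial), and the segmenter is
trained twice — once on Set M + Set D and once on Set M +
Set M_artificial — with both arms evaluated on the held-out
macroscopic test subset.  The report combines the Fréchet-distance /
Variation-Ratio table with the six-metric records of both arms.

All randomness flows from one root seed through named substreams, so a
rerun with the same config reproduces the report byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from . import evaluation, preprocessing, segmentation, synthetic, translation
from .preprocessing import ImageSample

__all__ = ["PipelineConfig", "run_pipeline", "assemble_training_sets",
           "report_to_markdown"]

ARMS = ("M_plus_D", "M_plus_Martificial")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full smoke-scale experiment."""

    synthetic: synthetic.SyntheticDatasetConfig = field(
        default_factory=lambda: synthetic.SyntheticDatasetConfig(
            n_images=16, image_size=32, artifact_probabilities={
                "dermo": {"dark_corners": 1.0},
                "macro": {"glare": 1.0},
            }))
    gan: translation.CycleGANConfig = field(
        default_factory=lambda: translation.CycleGANConfig(
            generator=translation.GeneratorSpec(input_size=32,
                                                base_channels=8,
                                                n_residual_blocks=2),
            discriminator=translation.DiscriminatorSpec(base_channels=8),
            max_epochs=12))
    seg_spec: segmentation.SegModelSpec = field(
        default_factory=lambda: segmentation.SegModelSpec.desk_scale(
            input_size=32))
    seg_train: segmentation.SegTrainConfig = field(
        default_factory=lambda: segmentation.SegTrainConfig(epochs=8))
    crop_dark_corners: bool = False
    embedder_seed: int = 0
    seed: int = 0


def _seed_stream(root_seed: int, name: str) -> int:
    digest = hashlib.sha256(f"{root_seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _prep_for_gan(samples, size: int, crop_corners: bool) -> list[ImageSample]:
    """Crop (optionally), resize and rescale samples to [-1, 1]."""
    out = []
    for s in samples:
        pixels, mask = s.pixels, s.mask
        if crop_corners and pixels.shape[0] >= 64:
            try:
                box = preprocessing.detect_dark_corners(pixels)
                pixels, mask = preprocessing.crop(pixels, box, mask)
            except preprocessing.UncroppableError:
                pass
        resized = preprocessing.resize_and_scale(pixels, size,
                                                 value_range=(-1.0, 1.0))
        if mask is not None:
            mask = preprocessing.resize_mask(mask, size)
        out.append(replace(s, pixels=resized, mask=mask))
    return out


def _to_unit(samples) -> list[ImageSample]:
    return [replace(s, pixels=(s.pixels + 1.0) / 2.0) for s in samples]


def assemble_training_sets(set_m, set_d, bundle: translation.TranslationBundle
                           ) -> tuple[list[ImageSample], list[ImageSample]]:
    """Build both experiment arms from ``[0, 1]`` samples.

    Arm one merges the macroscopic and dermoscopic sets as they are;
    arm two replaces the dermoscopic set with its translation into the
    macroscopic domain (Set M_artificial).  Counts are conserved and
    the translated samples keep their original masks.
    """
    set_m, set_d = list(set_m), list(set_d)
    scaled_d = [replace(s, pixels=s.pixels * 2.0 - 1.0) for s in set_d]
    translated = translation.translate(bundle, scaled_d, "dermo_to_macro")
    arm1 = set_m + set_d
    arm2 = set_m + _to_unit(translated)
    return arm1, arm2


def _metrics_dict(record: evaluation.MetricsRecord) -> dict:
    return {"TJA": record.tja, "JA": record.ja, "DI": record.di,
            "AC": record.ac, "SE": record.se, "SP": record.sp,
            "norm_FP": record.norm_fp, "norm_FN": record.norm_fn}


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None
                 ) -> dict:
    """Run both experiment arms end to end and return the report.

    When ``out_dir`` is given, intermediate datasets, the translator
    checkpoint, training histories, the JSON/Markdown report and a
    SHA-256 checksum manifest are written there.  The report content
    is a pure function of the config.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- stage 1: synthetic data
    syn_cfg = dataclasses.replace(config.synthetic,
                                  seed=_seed_stream(config.seed, "synthetic"))
    macro, dermo = synthetic.generate_dataset(syn_cfg)
    if out is not None:
        macro.save(out / "set_m")
        dermo.save(out / "set_d")

    gan_size = config.gan.generator.input_size
    macro_train = _prep_for_gan(macro.subset("train"), gan_size, False)
    dermo_train = _prep_for_gan(dermo.subset("train"), gan_size,
                                config.crop_dark_corners)
    macro_test = _prep_for_gan(macro.subset("test"), gan_size, False)

    # --- stage 2: translator
    gan_cfg = dataclasses.replace(config.gan,
                                  seed=_seed_stream(config.seed, "gan"))
    bundle = translation.train_cyclegan(dermo_train, macro_train, gan_cfg)
    if out is not None:
        translation.save_bundle(bundle, out / "translator.ckpt")
        bundle.history.to_csv(out / "translator_history.csv", index=False)

    trans_macro = translation.translate(bundle, dermo_train, "dermo_to_macro")
    trans_dermo = translation.translate(bundle, macro_train, "macro_to_dermo")

    # --- stage 3: distribution distances
    embedder = evaluation.RandomConvEmbedder(seed=config.embedder_seed)
    unit = {"macro": _to_unit(macro_train), "dermo": _to_unit(dermo_train),
            "trans_macro": _to_unit(trans_macro),
            "trans_dermo": _to_unit(trans_dermo)}
    stats = {k: evaluation.embed_images(v, embedder) for k, v in unit.items()}
    fid_ref = evaluation.frechet_distance(stats["macro"], stats["dermo"])
    fid_tm = evaluation.frechet_distance(stats["macro"], stats["trans_macro"])
    fid_td = evaluation.frechet_distance(stats["dermo"], stats["trans_dermo"])
    fid_table = [
        {"pair": "Set M/Set D (reference)", "fid": fid_ref, "vr": None},
        {"pair": "Set M/Set M_artificial", "fid": fid_tm,
         "vr": evaluation.variation_ratio(fid_ref, fid_tm)},
        {"pair": "Set D/Set D_artificial", "fid": fid_td,
         "vr": evaluation.variation_ratio(fid_ref, fid_td)},
    ]

    # --- stage 4: segmentation arms
    arm1, arm2 = assemble_training_sets(unit["macro"], unit["dermo"], bundle)
    seg_size = config.seg_spec.input_size

    def _prep_for_seg(samples):
        prepped = []
        for s in samples:
            pixels = preprocessing.resize_and_scale(s.pixels, seg_size)
            mask = preprocessing.resize_mask(s.mask, seg_size)
            prepped.append(replace(s, pixels=pixels, mask=mask))
        return prepped

    test_seg = _prep_for_seg(_to_unit(macro_test))
    arm_reports = {}
    for arm_name, arm_samples in zip(ARMS, (arm1, arm2)):
        seg_cfg = dataclasses.replace(
            config.seg_train, seed=_seed_stream(config.seed, f"seg:{arm_name}"))
        model, history = segmentation.train_segmenter(
            _prep_for_seg(arm_samples), seg_cfg, config.seg_spec)
        pairs = [(segmentation.predict_mask(model, s.pixels), s.mask)
                 for s in test_seg]
        record = evaluation.segmentation_metrics(pairs)
        arm_reports[arm_name] = {
            "n_train": len(arm_samples),
            "best_epoch": int(history.attrs["best_epoch"]),
            "final_val_dice": float(history["val_dice"].iloc[-1]),
            "metrics": _metrics_dict(record),
        }
        if out is not None:
            history.to_csv(out / f"seg_history_{arm_name}.csv", index=False)
            for s, (pred, _) in zip(test_seg, pairs):
                ov = evaluation.overlay(pred, s.mask)
                iio.imwrite(out / f"overlay_{arm_name}_{s.id}.png", ov)

    report = {
        "seed": config.seed,
        "n_images_per_domain": syn_cfg.n_images,
        "image_size": syn_cfg.image_size,
        "fid_table": fid_table,
        "arms": arm_reports,
    }
    if out is not None:
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
        (out / "report.md").write_text(report_to_markdown(report))
        checksums = {}
        for f in sorted(out.rglob("*")):
            if f.is_file() and f.name not in ("report.json", "report.md",
                                              "checksums.json"):
                checksums[str(f.relative_to(out))] = hashlib.sha256(
                    f.read_bytes()).hexdigest()
        (out / "checksums.json").write_text(
            json.dumps(checksums, indent=2, sort_keys=True))
    return report


def report_to_markdown(report: dict) -> str:
    """Render the report as human-readable Markdown tables."""
    lines = ["# Translation-augmentation experiment report", "",
             f"Seed {report['seed']}, {report['n_images_per_domain']} images "
             f"per domain at {report['image_size']} px.", "",
             "## Fréchet distance and Variation Ratio", "",
             "| Pair | FID | VR |", "| --- | --- | --- |"]
    for row in report["fid_table"]:
        vr = "" if row["vr"] is None else \
            f"{evaluation.round_half_away(row['vr']):.2f}"
        lines.append(f"| {row['pair']} | {row['fid']:.1f} | {vr} |")
    lines += ["", "## Segmentation arms", "",
              "| Arm | TJA | JA | DI | AC | SE | SP |",
              "| --- | --- | --- | --- | --- | --- | --- |"]
    for arm, data in report["arms"].items():
        m = data["metrics"]
        lines.append("| " + " | ".join(
            [arm] + [f"{m[k]:.4f}" for k in ("TJA", "JA", "DI", "AC",
                                             "SE", "SP")]) + " |")
    lines.append("")
    return "\n".join(lines)
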