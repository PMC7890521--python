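"""Desk-scale orchestration of the full study and its reports.

``run_study`` executes the whole chain on synthetic inputs: generate the
64-stimulus set and three area populations - train replicate saliency
networks on synthetic fixation data - embed the stimuli and record every
layer's activations (at a "partially trained" checkpoint and at the end of
training) - compute RDMs, layer-area correspondence profiles, partial
correlations and per-channel distributions - score the trained models'
saliency maps by fixation AUC - and write tidy TSV/JSON reports plus a
manifest sufficient to replay the run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, rsa, synthetic
from .network import (NetworkSpec, SaliencyNetwork, embed_on_canvas,
                      embed_stimulus, forward_record)
from .neural import RateTable, save_rate_table, zscore_per_neuron

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_study", "checkpoint_compare"]


@dataclass
class RunConfig:
    """Everything needed to replay a study run.

    Defaults describe the full-scale study design (64 stimuli in 8
    categories; V1/V4/IT populations of 691/494/294 neurons; 10 replicate
    models; training for 250 epochs with a 10-epoch "partially trained"
    checkpoint).  The tiny network spec and reduced image counts keep a
    desk-scale run tractable; scale knobs are explicit config fields.
    """

    seed: int = 0
    spec: str = "tiny"
    replicates: int = 10
    epochs: int = 250
    checkpoint_epochs: tuple = (10,)
    learning_rate: float = 5.0e-5
    batch_size: int = 20
    n_categories: int = 8
    per_category: int = 8
    stimulus_size: int = 16
    area_neurons: dict = field(default_factory=lambda: {
        "V1": 691, "V4": 494, "IT": 294})
    noise_sd: float = 1.0
    n_train_images: int = 30
    n_eval_images: int = 20
    points_per_image: int = 30
    sigma: float = 10.0
    rdm_form: str = "percentile"
    out_dir: str = "study_out"

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")
        if self.rdm_form not in {"raw", "percentile"}:
            raise ValueError("rdm_form must be 'raw' or 'percentile'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "checkpoint_epochs" in d:
            d["checkpoint_epochs"] = tuple(d["checkpoint_epochs"])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _fixation_sigma(cfg: RunConfig, canvas_wh) -> float:
    # the default 10 px is stated at 320x240; rescale for smaller canvases
    return cfg.sigma * canvas_wh[0] / 320.0


def _embed_all(stimuli, spec: NetworkSpec):
    w, h, _ = spec.input_shape
    embedded = []
    for im in stimuli.images:
        if im.shape[:2] == (256, 256) and (w, h) == (320, 240):
            embedded.append(embed_stimulus(im))
        else:
            embedded.append(embed_on_canvas(im, (w, h)))
    return embedded


def _layer_rdms(net, embedded, form: str, log: list) -> dict:
    """RDM per recording point from the stacked per-stimulus activations."""
    names = net.recording_points()
    flat = {name: [] for name in names}
    for sid, stim in enumerate(embedded, start=1):
        recs = forward_record(net, stim, stimulus_id=sid)
        for name in names:
            flat[name].append(recs[name].flatten())
    rdms = {}
    for name in names:
        patterns = np.stack(flat[name])
        try:
            rdm = rsa.compute_rdm(patterns, source=name)
        except rsa.DegenerateDataError as exc:
            log.append({"event": "degenerate_layer", "layer": name,
                        "detail": str(exc)})
            rdm = rsa.compute_rdm(patterns, source=name, drop_degenerate=True)
        rdms[name] = rsa.percentile_transform(rdm) if form == "percentile" \
            else rdm
    return rdms


def run_study(config: RunConfig, out_dir=None) -> dict:
    """Run the end-to-end study; returns the report bundle and writes files."""
    t0 = time.time()
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    policy_log: list[dict] = []
    rng = np.random.default_rng(config.seed)
    seeds = {k: int(s) for k, s in zip(
        ("stimuli", "areas", "fixations", "eval"),
        rng.integers(2 ** 31, size=4))}
    model_seeds = [int(s) for s in rng.integers(2 ** 31,
                                                size=config.replicates)]

    spec = NetworkSpec.bundled(config.spec) if isinstance(config.spec, str) \
        else config.spec
    canvas_wh = spec.input_shape[:2]

    # --- synthetic inputs ----------------------------------------------
    logger.info("stage=synthesize")
    stimuli = synthetic.generate_stimulus_set(
        config.n_categories, config.per_category, seed=seeds["stimuli"],
        size=config.stimulus_size)
    synthetic.save_stimulus_set(stimuli, out / "stimuli")

    area_tables = {}
    area_rdms = {}
    for i, (area, n_neurons) in enumerate(config.area_neurons.items()):
        table = synthetic.generate_neural_population(
            stimuli, area, n_neurons, noise_sd=config.noise_sd,
            seed=seeds["areas"] + i)
        save_rate_table(table, out / f"rates_{area}.tsv")
        z = zscore_per_neuron(table)
        rdm = rsa.compute_rdm(z.values, source=area)
        if config.rdm_form == "percentile":
            rdm = rsa.percentile_transform(rdm)
        area_tables[area] = table
        area_rdms[area] = rdm
        pd.DataFrame(rdm.matrix).to_csv(out / f"rdm_{area}.tsv", sep="\t",
                                        index=False, header=False)

    sigma = _fixation_sigma(config, canvas_wh)
    train_set = synthetic.generate_fixation_dataset(
        config.n_train_images, config.points_per_image,
        seed=seeds["fixations"], canvas_wh=canvas_wh)
    train_pairs = [(im, evaluation.make_fixation_map(rec, sigma=sigma).smoothed)
                   for im, rec in train_set]
    train_pairs = synthetic.mirror_augment(train_pairs)
    eval_set = synthetic.generate_fixation_dataset(
        config.n_eval_images, config.points_per_image, seed=seeds["eval"],
        canvas_wh=canvas_wh)

    # --- train replicates and record -----------------------------------
    X = np.stack([im for im, _ in train_pairs])
    y = np.stack([mp for _, mp in train_pairs])
    embedded = _embed_all(stimuli, spec)

    corr_rows = {"final": [], "checkpoint": []}
    partial_frames = []
    channel_frames = []
    auc_tables = {}
    loss_hist = {}
    for m, mseed in enumerate(model_seeds, start=1):
        logger.info("stage=train model=%d seed=%d", m, mseed)
        est = SaliencyNetwork(spec=spec, learning_rate=config.learning_rate,
                              batch_size=config.batch_size,
                              epochs=config.epochs, seed=mseed,
                              checkpoint_epochs=config.checkpoint_epochs)
        est.fit(X, y)
        loss_hist[f"model{m}"] = est.loss_history_

        nets = {"final": est.net_}
        for ep, snap in est.checkpoints_.items():
            nets[f"epoch{ep}"] = snap
        for tag, net in nets.items():
            rdms = _layer_rdms(net, embedded, config.rdm_form, policy_log)
            table = pd.DataFrame(
                [{"layer": lid, "area": area,
                  "r": rsa.correspondence(rdms[lid], area_rdms[area])}
                 for lid in rdms for area in area_rdms])
            table["model"] = m
            if tag == "final":
                corr_rows["final"].append(table)
                pf = rsa.partial_correlation_profile(rdms, area_rdms)
                pf["model"] = m
                partial_frames.append(pf)
            else:
                table["checkpoint"] = tag
                corr_rows["checkpoint"].append(table)

        # per-channel analysis on the final model, deepest conv layer
        conv_names = [d["name"] for d in spec.layers if d["kind"] == "conv"]
        last_conv = conv_names[-1] + "_relu"
        acts = np.stack([
            forward_record(est.net_, stim)[last_conv].values
            for stim in embedded])
        ch = rsa.per_channel_correspondence(acts, area_rdms["V1"],
                                            form=config.rdm_form)
        ch["model"] = m
        ch["layer"] = last_conv
        channel_frames.append(ch)
        n_excl = int(ch["excluded"].sum())
        if n_excl:
            policy_log.append({"event": "excluded_channels", "model": m,
                               "layer": last_conv, "count": n_excl})

        auc_tables[f"model{m}"] = evaluation.mean_auc(
            lambda im: est.net_.predict_map(im), eval_set)["per_image"]

    # --- reports --------------------------------------------------------
    profile = rsa.profile_over_models(
        [t.drop(columns="model") for t in corr_rows["final"]])
    profile.to_csv(out / "correspondence_profile.tsv", sep="\t", index=False)
    pd.concat(corr_rows["final"]).to_csv(out / "correspondence_by_model.tsv",
                                         sep="\t", index=False)
    ckpt_profile = None
    if corr_rows["checkpoint"]:
        ckpt_profile = rsa.profile_over_models(
            [t.drop(columns=["model", "checkpoint"])
             for t in corr_rows["checkpoint"]])
        ckpt_profile.to_csv(out / "correspondence_profile_checkpoint.tsv",
                            sep="\t", index=False)
        delta = checkpoint_compare(ckpt_profile, profile)
        delta.to_csv(out / "checkpoint_delta.tsv", sep="\t", index=False)
    partials = pd.concat(partial_frames)
    partials.to_csv(out / "partial_correlation.tsv", sep="\t", index=False)
    channels = pd.concat(channel_frames)
    channels.to_csv(out / "per_channel.tsv", sep="\t", index=False)

    if len(auc_tables) >= 2:
        comparison = evaluation.compare_models(auc_tables)
        comparison["summary"].to_csv(out / "auc_summary.tsv", sep="\t",
                                     index=False)
        comparison["pairwise"].to_csv(out / "auc_pairwise.tsv", sep="\t",
                                      index=False)
    else:
        only = next(iter(auc_tables.values()))
        comparison = {"summary": pd.DataFrame([{
            "model": "model1", "mean_auc": only["auc"].mean(),
            "sem": 0.0, "n_images": len(only)}]),
            "pairwise": None, "anova_F": np.nan, "anova_p": np.nan}
        comparison["summary"].to_csv(out / "auc_summary.tsv", sep="\t",
                                     index=False)
    pd.concat([t.assign(model=k) for k, t in auc_tables.items()]).to_csv(
        out / "auc_per_image.tsv", sep="\t", index=False)
    pd.DataFrame(loss_hist).to_csv(out / "loss_history.tsv", sep="\t",
                                   index_label="epoch")

    manifest = {
        "config": asdict(config), "config_hash": config.config_hash(),
        "stage_seeds": seeds, "model_seeds": model_seeds,
        "recording_points": [d["name"] for d in spec.layers],
        "policy_log": policy_log, "wall_time_s": round(time.time() - t0, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return {"profile": profile, "checkpoint_profile": ckpt_profile,
            "partial": partials, "channels": channels,
            "auc": comparison, "manifest": manifest,
            "area_rdms": area_rdms, "loss_history": loss_hist}


def checkpoint_compare(profile_early: pd.DataFrame,
                       profile_final: pd.DataFrame) -> pd.DataFrame:
    """Per-(layer, area) correspondence difference, trained minus early.

    Both inputs are profile tables as produced by
    :func:`rsa.profile_over_models` over identical layer sets.
    """
    key = ["layer", "area"]
    a = profile_early.set_index(key)
    b = profile_final.set_index(key)
    if not a.index.equals(b.index):
        raise ValueError("checkpoint profiles cover different (layer, area) sets")
    out = b.reset_index()[key].copy()
    out["mean_r_final"] = b["mean_r"].to_numpy()
    out["mean_r_early"] = a["mean_r"].to_numpy()
    out["delta"] = out["mean_r_final"] - out["mean_r_early"]
    return out
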