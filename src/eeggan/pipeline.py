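"""End-to-end desk-scale experiment: simulate -> preprocess -> GAN ->
select -> classify -> alarm statistics.

This is the orchestration used by the acceptance script and the end-to-end
test: a compact, CPU-sized version of the full study protocol.  Real
pre-ictal/interictal segments are simulated and turned into 64x64 spectrogram
images; a classifier trained and tested on real images gives the TRTR
reference; a DCGAN trained on the real pre-ictal images synthesizes pre-ictal
samples which are screened by the one-class SVM; a second classifier trained
on synthesized pre-ictal + real interictal images and tested on the same real
test split gives the TSTR row; finally the TSTR model scores a simulated
continuous 10 h timeline and its event-level prediction is compared against
the chance-level alarm predictor.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np

from . import cesp, dcgan, evaluation as ev, preprocess as pp, selection, synthetic as sy

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeskExperimentConfig:
    n_per_class: int = 200
    gan_epochs: int = 100
    gan_lr: float = 1e-3
    n_generated: int = 150
    test_fraction: float = 0.25
    timeline_h: float = 10.0
    timeline_seizures: int = 2
    sph: float = 10.0
    sop: float = 30.0
    min_accepted_for_training: int = 32


def run_desk_experiment(seed: int,
                        cfg: DeskExperimentConfig = DeskExperimentConfig(),
                        ) -> dict:
    """Run the full pipeline at desk scale; returns a flat metrics dict."""
    rng = np.random.default_rng(seed)
    sim = sy.PRESETS["desk"].replace(seed=int(rng.integers(2**31)))
    cesp_cfg = dataclasses.replace(cesp.DESK_CESP, seed=int(rng.integers(2**31)))
    gan_seed = int(rng.integers(2**31))
    sample_seed = int(rng.integers(2**31))

    segments = sy.simulate_dataset(sim, cfg.n_per_class)
    images = pp.preprocess_dataset(segments, pp.DESK_PREPROCESS)
    train_imgs, test_imgs = ev.time_disjoint_split(images, cfg.test_fraction)
    test_labels = [im.label for im in test_imgs]

    # TRTR reference
    trtr_model = cesp.train_plain(train_imgs, cesp_cfg)
    trtr = ev.segment_metrics(
        cesp.predict(trtr_model, test_imgs, normalize=True), test_labels)

    # DCGAN on the real pre-ictal training images
    real_pre = [im for im in train_imgs if im.label == sy.PREICTAL]
    gan = dcgan.build_gan(dcgan.DESK_GENERATOR, dcgan.DESK_DISCRIMINATOR,
                          64, sy.PREICTAL, seed=gan_seed)
    dcgan.train(real_pre, gan, batch_size=32, lr=cfg.gan_lr,
                max_epochs=cfg.gan_epochs, seed=gan_seed)
    generated = dcgan.sample(gan, cfg.n_generated, seed=sample_seed)

    # one-class SVM screening
    selector = selection.fit_ocsvm(real_pre, selection.SelectorConfig())
    sel_res = selection.filter_samples(selector, generated)
    synth_pre = sel_res.accepted
    if len(synth_pre) < cfg.min_accepted_for_training:
        log.warning("only %d generated samples accepted; training on all %d",
                    len(synth_pre), len(generated))
        synth_pre = generated

    # TSTR: synthesized pre-ictal + real interictal for training,
    # same real test split for testing
    real_inter = [im for im in train_imgs if im.label == sy.INTERICTAL]
    tstr_model = cesp.train_plain(synth_pre + real_inter, cesp_cfg)
    tstr = ev.segment_metrics(
        cesp.predict(tstr_model, test_imgs, normalize=True), test_labels)

    # continuous timeline, scored by the TSTR model
    timeline = sy.simulate_timeline(sim, cfg.timeline_h, cfg.timeline_seizures,
                                    cfg.sph, cfg.sop)
    tl_segments = sy.timeline_segments(sim, timeline)
    tl_images = pp.preprocess_dataset(tl_segments, pp.DESK_PREPROCESS)
    tl_scores = cesp.predict(tstr_model, tl_images, normalize=True)
    alarm_cfg = ev.AlarmConfig(sph=cfg.sph, sop=cfg.sop, threshold=0.5)
    alarm = ev.alarm_evaluate(timeline,
                              [im.t_start for im in tl_images], tl_scores,
                              alarm_cfg)
    chance = ev.chance_test(alarm.n_predicted, alarm.n_seizures,
                            alarm.fpr_per_h, cfg.sop)

    return {
        "n_images": len(images),
        "n_test": len(test_imgs),
        "trtr_auc": trtr.auc,
        "trtr_sensitivity": trtr.sensitivity,
        "trtr_accuracy": trtr.accuracy,
        "tstr_auc": tstr.auc,
        "tstr_sensitivity": tstr.sensitivity,
        "tstr_accuracy": tstr.accuracy,
        "auc_gap": abs(trtr.auc - tstr.auc),
        "gan_batches": gan.train_state.batch,
        "gan_stopped_early": gan.train_state.stopped_early,
        "acceptance_rate": sel_res.acceptance_rate,
        "n_accepted": len(sel_res.accepted),
        "event_sensitivity": alarm.sensitivity_event,
        "n_seizures": alarm.n_seizures,
        "n_predicted": alarm.n_predicted,
        "false_alarms": alarm.false_alarms,
        "interictal_hours": alarm.interictal_hours,
        "fpr_per_h": alarm.fpr_per_h,
        "chance_alarm_probability": chance.P,
        "chance_p_value": chance.p_value,
        "beats_chance": chance.reject_null,
    }
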