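"""Shared fixtures: synthetic images and videos, generated at test time.

Session scope keeps the expensive DIC-bearing videos to one synthesis
and (where shared) one analysis per run.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

import cardiostrain as cs


@pytest.fixture(scope="session")
def speckle_ref():
    """Smooth, band-limited speckle frame for DIC shift tests."""
    sp = ndimage.gaussian_filter(cs.generate_speckle((200, 200), 0.1, rng_seed=2), 1.0)
    return 0.15 + 0.85 * sp


@pytest.fixture(scope="session")
def chevron_spec():
    return cs.PatternSpec()


@pytest.fixture(scope="session")
def chevron_mask(chevron_spec):
    return cs.generate_chevron_mask(chevron_spec)


@pytest.fixture(scope="session")
def uniaxial_video():
    """One-beat uniaxial contraction video at the standard field size.

    Peak prescribed contractile strain 0.05, 42 BPM raised-cosine pulse,
    11.02 fps.  Short duration: enough frames to bracket the systolic
    peak, which is all the strain-recovery checks need.
    """
    pattern = cs.PatternSpec()
    chevron = cs.generate_chevron_mask(pattern)
    speckle = cs.generate_speckle(chevron.shape, 0.1, rng_seed=3)
    wf = cs.ContractionWaveformSpec(
        rate=42.0, peak_strain=0.05, duration=1.3, frame_rate=11.02, rng_seed=3
    )
    seq, truth = cs.synthesize_video(chevron, speckle, wf, "uniaxial_contraction")
    return seq, truth


@pytest.fixture(scope="session")
def uniaxial_analysis(uniaxial_video):
    seq, truth = uniaxial_video
    return cs.analyze_sequence(seq), truth


@pytest.fixture(scope="session")
def beating_video():
    """Two-beat video at a reduced field size for rate recovery."""
    pattern = cs.PatternSpec(field_size=(288, 288))
    chevron = cs.generate_chevron_mask(pattern)
    speckle = cs.generate_speckle(chevron.shape, 0.1, rng_seed=7)
    wf = cs.ContractionWaveformSpec(
        rate=42.0, peak_strain=0.05, duration=2.7, frame_rate=11.02, rng_seed=7
    )
    seq, truth = cs.synthesize_video(chevron, speckle, wf, "uniaxial_contraction")
    return seq, truth
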