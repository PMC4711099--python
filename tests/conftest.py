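import numpy as np
import pytest

from lingua_rt import (
    PhantomConfig,
    build_profile_grid,
    fig2_like_config,
    generate_phantom,
    render_exercise_audio,
)
from lingua_rt.synthetic import default_note_onsets

SR = 22050


@pytest.fixture(scope="session")
def exercise_audio():
    """Clean rendering of the full ascending exercise (11 × 0.9 s from 0.5 s)."""
    onsets = default_note_onsets()
    wave = render_exercise_audio(onsets, sr=SR, total_duration_s=11.0)
    return wave, SR, onsets


@pytest.fixture(scope="session")
def fig2_film():
    """Noiseless film with the printed onset-frame anchors, plus its truth."""
    cfg = fig2_like_config()
    film, truth = generate_phantom(cfg)
    return cfg, film, truth


@pytest.fixture(scope="session")
def default_grid():
    return build_profile_grid(PhantomConfig().landmarks)


@pytest.fixture()
def short_phantom_config():
    """Small fast phantom: 6 s / 180 frames, 11 notes of 0.5 s from t=0.3 s."""
    onsets = [0.3 + 0.5 * k for k in range(11)]
    return PhantomConfig(
        n_frames=180,
        note_onsets_s=onsets,
        note_duration_s=0.5,
        noise_sd=0.0,
        streak_rate=0.0,
        transient_px=0.0,
    )


def rm_table(values_by_group):
    """Long-format table from {group: (n_subjects × k) array}."""
    import pandas as pd

    rows = []
    for g, vals in values_by_group.items():
        vals = np.asarray(vals, dtype=float)
        for i in range(vals.shape[0]):
            for h in range(vals.shape[1]):
                rows.append(
                    dict(
                        subject_id=f"{g}{i:02d}",
                        group=g,
                        harmonic=h + 1,
                        value_px=vals[i, h],
                    )
                )
    return pd.DataFrame(rows)
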