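import numpy as np
import pytest

from dyadsync.ras import RASResponse
from dyadsync.recording import RawDyadRecording, SubjectRecording
from dyadsync.schedule import make_schedule
from dyadsync.simulate import SimConfig, noise_free, simulate_dyad


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def build_recording(
    gains_a=None,
    cvs_a=None,
    channels=(4, 6, 13, 14),
    n_samples=200,
    sampling_rate=7.81,
    seed=0,
):
    """Minimal hand-built recording for validation-level tests."""
    r = np.random.default_rng(seed)
    gains_a = gains_a or {}
    cvs_a = cvs_a or {}
    subjects = []
    for label in ("a", "b"):
        od = {
            ch: {760: r.normal(size=n_samples), 850: r.normal(size=n_samples)}
            for ch in channels
        }
        gain = {ch: float(gains_a.get(ch, 3.0)) if label == "a" else 3.0 for ch in channels}
        cv = {
            ch: (
                {760: float(cvs_a.get(ch, 2.0)), 850: 2.0}
                if label == "a"
                else {760: 2.0, 850: 2.0}
            )
            for ch in channels
        }
        subjects.append(
            SubjectRecording(
                label=label,
                od=od,
                gain=gain,
                cv=cv,
                ras=RASResponse((4, 4, 4, 4, 4, 4, 4)),
            )
        )
    return RawDyadRecording(
        dyad_id="toy",
        sequence_label="A",
        sampling_rate=sampling_rate,
        subjects=(subjects[0], subjects[1]),
        video_onsets_s=(10.0,),
    )


@pytest.fixture(scope="session")
def clean_dyad():
    """A noise-free, fully coupled dyad (both subjects identical by design)."""
    from dyadsync.simulate import CouplingLink

    cfg = noise_free(SimConfig(seed=5, coupling=CouplingLink(beta0=1.0, beta1=0.0, sigma=0.0)))
    return simulate_dyad(cfg, delta_sat=0.5, dyad_seed=11, sequence_label="A")


@pytest.fixture(scope="session")
def noisy_dyad():
    """One dyad under the default study conditions."""
    return simulate_dyad(SimConfig(seed=3), delta_sat=0.6, dyad_seed=42, sequence_label="B")


@pytest.fixture(scope="session")
def schedule_a():
    return make_schedule("A")
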