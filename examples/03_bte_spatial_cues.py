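"""Effect of behind-the-ear microphones on spatial cues.

Renders speech-shaped noise from a lateral source through the unaided and
the aided (BTE-transformed) BRIR and compares the interaural cues: the
aided condition should show ~5 dB more ILD above 2 kHz and a slightly
smaller ITD.
"""

import scipy.signal as sps

from binratio import (
    BinauralSignal,
    SceneConfig,
    apply_bte_transform,
    cue_profile,
    design_gammatone_bank,
    generate_ssn,
    measure_broadband_itd,
    simulate_brir,
)
from binratio.noise import pink_reference

rate = 44_100.0
brir = simulate_brir(SceneConfig(rate=rate, seed=3), azimuth=90.0)
aided = apply_bte_transform(brir)
ssn = generate_ssn(pink_reference(5.0, rate, 0), 3.0, seed=1)
bank = design_gammatone_bank(80.0, 10_000.0, 2.0)


def rendered(b):
    left = sps.fftconvolve(ssn.samples, b.response.left.samples)[: len(ssn)]
    right = sps.fftconvolve(ssn.samples, b.response.right.samples)[: len(ssn)]
    return BinauralSignal.from_arrays(left, right, rate)


for label, b in (("unaided", brir), ("aided  ", aided)):
    profile = cue_profile(rendered(b), bank)
    print(f"{label}: mean ILD >2 kHz {profile.mean_ild_above(2000.0):+6.2f} dB, "
          f"ITD {measure_broadband_itd(b)*1e6:+6.1f} us, "
          f"mean coherence {profile.summary()['mean_coherence']:.3f}")
# ILD grows by ~5 dB in magnitude (head-baffle boost at the exposed BTE
# microphone) and the ITD shrinks by the configured factor 0.9
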