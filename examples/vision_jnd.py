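"""Predator-vision analysis of a synthetic hyperspectral scene.

Builds a 16-band (360-660 nm) scene - textured green background with a
butterfly-shaped patch - and computes the three conspicuousness measures:
percent luminance change, granularity-spectrum KL divergence, and chromatic
JND under receptor-noise-limited trichromat and tetrachromat observers.
A butterfly whose reflectance matches the background scores ~0 on all
three; a spectrally shifted one is conspicuous, most so for the
UV-sensitive tetrachromat.
"""

import numpy as np

from mimicrylab import synth, vision

wavelengths = np.linspace(360, 660, 16)
# a UV-shifted, brighter reflectance for the conspicuous case
shifted = tuple(0.6 * np.exp(-0.5 * ((wavelengths - 420) / 70) ** 2) + 0.2)

for label, kwargs in {
    "background-matched": dict(butterfly_scale=1.0),
    "uv-shifted": dict(butterfly_spectrum=shifted),
}.items():
    cube, mask, truth = synth.generate_scene(
        synth.SceneSpec(texture_amplitude=0.15, seed=5, **kwargs)
    )
    lum_mean, lum_sd = vision.percent_luminance_change(cube, mask)
    lum = vision.luminance_map(cube)
    kl = vision.kl_divergence(
        vision.granularity_spectrum(lum, mask),
        vision.granularity_spectrum(lum, ~mask),
    )
    print(f"{label} butterfly:")
    print(f"  luminance change: {lum_mean:+.1f}% +/- {lum_sd:.1f}%")
    print(f"  granularity KL(butterfly || background): {kl:.4f}")
    for observer, rec in {
        "trichromat": vision.ReceptorModel.trichromat(cube.wavelengths),
        "tetrachromat": vision.ReceptorModel.tetrachromat(cube.wavelengths),
    }.items():
        res = vision.jnd_map(cube, mask, rec)
        print(f"  {observer} JND: mean {res.mean:.2f}, sd {res.sd:.2f}")
print(
    "\nJND < 1 means the patch is chromatically indistinguishable from the\n"
    "average background for that observer: the background-matched butterfly\n"
    "scores ~0 JND while the UV-shifted one stands out, most for the\n"
    "UV-sensitive tetrachromat.  The KL term is identical in both cases\n"
    "because it measures spatial texture (a flat patch against 1/f leaf\n"
    "litter), independent of the spectral difference."
)
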