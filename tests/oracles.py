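"""Independent reference implementations used as test oracles."""

import numpy as np

from musmb.ms import PROTON_MASS, ReconSpectrum


def brute_force_reconstruction(spectrum, input_range, output_range, step):
    """Nested-loop zero-charge transform, deliberately naive."""
    lo, hi = input_range
    masses = output_range[0] + step * np.arange(
        int(round((output_range[1] - output_range[0]) / step)) + 1
    )
    out = np.zeros_like(masses)
    for i, m in enumerate(masses):
        for z in range(1, 60):
            mz = (m + z * PROTON_MASS) / z
            if lo <= mz <= hi:
                out[i] += float(
                    np.interp(mz, spectrum.mz, spectrum.intensity, left=0.0, right=0.0)
                )
    return ReconSpectrum(masses, out)


def analytic_first_moment(col, kd, flow_ul_min):
    """LRMP pulse retention: V·[ε_int + (1-ε_int)·ε_p·K_d]/Q, seconds."""
    return col.volume_ul * col.accessible_porosity(kd) / (flow_ul_min / 60.0)
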