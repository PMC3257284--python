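"""Miller units from beta-Gal assays, and promoter activity.

Endpoint and kinetic readouts of the same linear color-development curve
agree; promoter activity corrects expression for dilution by growth.
"""

import numpy as np

from lacprofiler.assays import (
    BetaGalEndpoint, BetaGalKinetic, miller_endpoint, miller_kinetic,
    promoter_activity,
)

times = np.arange(0, 31, 3.0)            # minutes
od420 = 0.012 * times                    # linear color development
kin = BetaGalKinetic(times, od420, od600=0.45, volume=0.02)
end = BetaGalEndpoint(od420[-1], od600=0.45, volume=0.02, reaction_time=times[-1])

m_kin, m_end = miller_kinetic(kin), miller_endpoint(end)
print(f"kinetic estimate:  {m_kin:.1f} Miller units")
print(f"endpoint estimate: {m_end:.1f} Miller units")

pa = promoter_activity(m_kin, doubling_rate=0.68)
print(f"promoter activity: {pa.activity:.1f} Miller x doublings/hr")
print()
print("Miller units normalize color development by cell density, assay")
print("volume and time; multiplying by the doubling rate converts steady-")
print("state enzyme level into a synthesis-rate-like promoter activity.")
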