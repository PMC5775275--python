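"""Independent hand-coded oracle for the asparagine synthetase ODE system.

Written directly from the eleven rate equations of the mechanism, term by
term, with no use of the package's network compiler.  Species order matches
``asnkin.asn_model.SPECIES``:
AMP, Asn, ASNe, ASNe-Gln, ASNe-NH3, Asp, ATP, bAsp-AMP-ASNe-NH3, Gln, Glu, Mg2+.
"""

import numpy as np


def hand_coded_rhs(params):
    k1 = params["k1"]
    k2 = params["k2"]
    k3 = params["k3"]
    k4 = params["k4"]
    kD = params["kD"]

    def rhs(t, y):
        (AMP, Asn, ASNe, ASNeGln, ASNeNH3, Asp, ATP, Beta, Gln, Glu, Mg) = y
        dGln = -(k1 * Gln * ASNe)
        dASNeGln = (k1 * Gln * ASNe) - (k2 * ASNeGln)
        dASNe = (k4 * Beta) + (kD * ASNeNH3) - (k1 * Gln * ASNe)
        dGlu = k2 * ASNeGln
        dASNeNH3 = (k2 * ASNeGln) - (k3 * ASNeNH3 * Asp * Mg * ATP) - (kD * ASNeNH3)
        dAsp = -(k3 * ASNeNH3 * Asp * Mg * ATP)
        dBeta = (k3 * ASNeNH3 * Asp * Mg * ATP) - (k4 * Beta)
        dAsn = k4 * Beta
        dAMP = k4 * Beta
        dATP = 0.0
        dMg = 0.0
        return np.array(
            [dAMP, dAsn, dASNe, dASNeGln, dASNeNH3, dAsp, dATP, dBeta, dGln, dGlu, dMg]
        )

    return rhs
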