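"""Exception types shared across the package."""


class SelexdynError(Exception):
    """Base class for all selexdyn errors."""


class DegenerateRoundError(SelexdynError):
    """Raised when the mean recovery probability of a round is zero.

    If no sequence at all is recovered, the frequency recursion
    p_i(n) = p_i(n-1) R_i / R-bar is undefined and the experiment has
    failed; this is reported rather than silently returning NaNs.
    """


class TieError(SelexdynError):
    """Raised when a dominant species is requested but the top frequencies tie."""
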