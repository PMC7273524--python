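"""Exception types shared across the package.

Two failure modes are kept distinct throughout the pipeline:

* :class:`InvalidParameterError` — the caller asked for something
  meaningless (negative duration, heritability outside [0, 1], ...).
  These are programming errors and always raise.
* :class:`QCError` — the *data* failed a quality-control rule (too few
  beats in a window, no descending T-limb, non-positive RR change, ...).
  Cohort-level drivers catch these per record and log the reason instead
  of aborting the whole analysis.
"""


class InvalidParameterError(ValueError):
    """A parameter value outside its documented domain."""


class QCError(RuntimeError):
    """A record failed a quality-control rule.

    Parameters
    ----------
    reason:
        Short machine-readable tag (e.g. ``"too_few_beats"``).
    detail:
        Optional free-text elaboration.
    """

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        self.detail = detail
        super().__init__(f"{reason}: {detail}" if detail else reason)


class CollinearityError(ValueError):
    """Design matrix is rank deficient where full rank is required."""
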