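"""Exception hierarchy for sdi3d."""


class Sdi3dError(Exception):
    """Base class for all sdi3d errors."""


class DomainError(Sdi3dError):
    """Invalid or degenerate domain (empty mask, non-watertight mesh, ...)."""


class OutsideDomainError(Sdi3dError):
    """A query point lies outside the domain."""


class PackingError(Sdi3dError):
    """Objects could not be placed without violating hard-core/containment
    constraints within the configured number of restarts."""


class EmptyOrbitError(Sdi3dError):
    """An orbital iso-distance surface is empty (orbit distance exceeds the
    largest boundary distance available in the domain)."""


class PatternFormatError(Sdi3dError):
    """Malformed pattern file or invalid pattern contents."""
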