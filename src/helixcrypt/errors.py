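"""Exception hierarchy shared across the package.

Every error raised by helixcrypt derives from :class:`HelixcryptError`, so
callers (and the CLI exit-code map) can distinguish our failures from bugs.
"""


class HelixcryptError(Exception):
    """Base class for all helixcrypt errors."""


class InvalidInputError(HelixcryptError, ValueError):
    """A caller-supplied value violates an operation's precondition."""


class AlphabetError(HelixcryptError, ValueError):
    """A sequence contains symbols outside its declared alphabet, or a
    DNA-only operation received RNA (or vice versa)."""


class FormatError(HelixcryptError, ValueError):
    """A serialized ciphertext, header, or coded stream is malformed."""


class ConfigError(HelixcryptError, ValueError):
    """A configuration object violates its invariants."""


class ConstraintError(HelixcryptError, RuntimeError):
    """Biochemical constraint enforcement could not find a compliant
    encoding within the attempt budget."""


class ECCDecodeError(HelixcryptError, RuntimeError):
    """The Reed-Solomon decoder could not correct the received word.

    Raised instead of returning silently truncated or corrupted data.
    """
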