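a
an
the
is
are
was
were
be
been
being
am
do
does
did
to
of
in
on
at
by
for
with
from
as
that
this
these
those
which
what
who
whom
whose
where
when
how
all
any
each
me
my
we
our
us
you
your
it
its
their
there
have
has
had
and
or
so
such
please
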