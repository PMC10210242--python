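 &FCI NORB=   2,NELEC= 2,MS2=0,
  ORBSYM=1,1,
  ISYM=1,
 &END
 0.6747559268144483    1    1    1    1
 8.326672684688674e-17    1    1    2    1
 0.6637114013508135    1    1    2    2
 6.938893903907228e-17    2    1    1    1
 0.181210462015197    2    1    2    1
 8.326672684688674e-17    2    1    2    2
 0.6637114013508136    2    2    1    1
 3.05311331771918e-16    2    2    2    1
 0.6976515044904622    2    2    2    2
 -1.253309786645977    1    1  0  0
 -4.697181385037046e-16    2    1  0  0
 -0.4750688487721779    2    2  0  0
 0.7151043390810812  0  0  0  0
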