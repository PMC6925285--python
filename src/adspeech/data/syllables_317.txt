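ai
an
ang
ao
bai
ban
bang
bei
ben
beng
bi
biao
bie
bin
bo
bu
ca
cai
cang
cao
ce
ceng
cha
chai
chan
chao
che
chen
chi
chong
chou
chu
chuai
chuan
chuang
chui
chuo
ci
cong
cu
cuan
cui
cun
da
dai
dan
dao
de
dei
den
di
dia
dian
die
ding
diu
dong
du
duan
dui
dun
e
ei
en
er
fa
fan
fang
fen
feng
fo
fu
ga
gai
gan
gao
ge
gei
geng
gong
gou
gu
guai
guan
guang
gun
guo
ha
hai
hang
hao
he
hei
heng
hong
hou
hua
huai
huan
huang
hun
huo
ji
jian
jiang
jiao
jie
jing
jiong
jiu
juan
jue
jun
ka
kan
kang
kao
ke
keng
kong
kou
kua
kuai
kuan
kuang
kun
kuo
la
lan
lang
lao
le
leng
li
lia
liang
liao
lie
lin
liu
long
lou
luan
lun
luo
lv
ma
mai
man
mang
me
mei
men
mi
mian
miao
mie
ming
miu
mo
mu
na
nai
nan
nao
ne
nei
neng
ni
nian
niang
nie
nin
ning
niu
nou
nu
nuan
nv
nve
o
ou
pai
pan
pang
pei
pen
peng
pi
piao
pie
pin
po
pou
pu
qi
qian
qiang
qiao
qin
qing
qiong
qiu
quan
que
qun
ran
rao
re
ren
ri
rong
rou
ru
ruan
rui
run
sa
sai
san
sang
se
sen
seng
shai
shan
shang
shao
shei
shen
sheng
shi
shu
shua
shuai
shuang
shui
shun
shuo
song
sou
su
sui
sun
suo
ta
tan
tang
tao
teng
ti
tian
tiao
ting
tong
tou
tuan
tui
tun
tuo
wai
wan
wang
wei
weng
wo
wu
xia
xian
xiang
xiao
xin
xing
xiong
xu
xuan
xue
xun
yan
yang
yao
yi
yin
ying
yong
yu
yuan
yue
yun
zai
zan
zang
ze
zei
zen
zeng
zhai
zhan
zhang
zhe
zhei
zhen
zheng
zhong
zhou
zhu
zhuai
zhuan
zhuang
zhui
zhuo
zi
zong
zu
zuan
zui
zun
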