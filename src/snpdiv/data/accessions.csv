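name,status,origin,maturation
Sanyuehong,old_cultivar,GD,EEM
Dazao,old_cultivar,GD,EM
Zhongshanzhuanyuanhong,old_cultivar,GD,EM
Shuidong,old_cultivar,GD,EM
Feizixiao,old_cultivar,GD,EM
Guiwei,old_cultivar,GD,MLM
Nuomici,old_cultivar,GD,MLM
Huaizhi,old_cultivar,GD,MLM
Heiye,old_cultivar,GD,MLM
Zengchengjinfeng,old_cultivar,GD,MLM
Huidongsijili,old_cultivar,GD,MLM
Baitangying,old_cultivar,GD,MLM
Yuhebao,old_cultivar,GX,EEM
Siyueban,old_cultivar,GX,EEM
Siyuehong,old_cultivar,GX,EM
Zaoshuheiye,old_cultivar,GX,EM
Guangxitangbo,old_cultivar,GX,MLM
Qinzhouhongli,old_cultivar,GX,MLM
Jizuili,old_cultivar,GX,MLM
Yuanhong,old_cultivar,FJ,EM
Baibozaohong,old_cultivar,FJ,EM
Dachenzi,old_cultivar,FJ,EM
Lanzhu,old_cultivar,FJ,MLM
Edanli,old_cultivar,HN,MLM
Wuheli,old_cultivar,HN,MLM
Ziniangxi,old_cultivar,HN,MLM
Suanlizhi,old_cultivar,SC,EEM
Dahongpao,old_cultivar,SC,EM
Tuoti,old_cultivar,SC,MLM
Yuanli-1,old_cultivar,YN,EEM
Yuanzao,old_cultivar,YN,EEM
Yuanyang-1,old_cultivar,YN,EEM
Yuanyang-2,old_cultivar,YN,EEM
Nanxizaosheng,old_cultivar,TW,EM
Xiaomi,old_cultivar,VN,MLM
Honghua,old_cultivar,VN,MLM
KALOKA,old_cultivar,TL,MLM
Zaoli1hao,modern_cultivar,GD,EEM
Guizaoli,modern_cultivar,GX,EM
Liaoyuan,modern_cultivar,YN,EM
Xinjinfeng,modern_cultivar,GD,MLM
Feicui,modern_cultivar,GD,MLM
Guanyinlv,modern_cultivar,GD,MLM
Beiyuanlv,modern_cultivar,GD,MLM
Bingli,modern_cultivar,GD,MLM
Lingnong,modern_cultivar,GD,MLM
Guishuang,modern_cultivar,GD,MLM
Maguili,modern_cultivar,GD,MLM
Hongxiuqiu,modern_cultivar,GD,MLM
Fengjitou,modern_cultivar,GD,MLM
Wanxiangyu,modern_cultivar,GD,MLM
Diwangnuo,modern_cultivar,GD,MLM
Caomeili,modern_cultivar,GX,MLM
Guifeihong,modern_cultivar,GX,MLM
Yutanmili,modern_cultivar,HN,MLM
A16,hybrid,-,EEM
08-1,hybrid,-,EEM
06-9,hybrid,-,EM
Zaogui,hybrid,-,EM
Zaonuo,hybrid,-,EM
Guinuo-1,hybrid,-,MLM
Guinuo-2,hybrid,-,MLM
Guinuo-3,hybrid,-,MLM
Honggui,hybrid,-,MLM
Guihong,hybrid,-,MLM
05-4,hybrid,-,MLM
08-7,hybrid,-,MLM
YNW01,wild,YN,EEM
YNW02,wild,YN,EEM
GXDXW01,wild,DX-GX,EEM
GXDXW02,wild,DX-GX,EEM
GXDXW03,wild,DX-GX,EEM
GXBBW01,wild,BB-GX,MLM
GXBBW02,wild,BB-GX,MLM
GXBBW03,wild,BB-GX,MLM
GDW01,wild,GD,MLM
GDW02,wild,GD,MLM
GDW03,wild,GD,MLM
GDW4,wild,GD,MLM
HNW01,wild,HN,MLM
HNW02,wild,HN,MLM
HNW03,wild,HN,MLM
VNW01,wild,VN,EEM
VNW02,wild,VN,EEM
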